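"""Membrane mass transfer: conductance, flux, simulation and inverse problems."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutdial import (
    CalibrationRun,
    FoulingProfile,
    InvalidRegimeError,
    KineticParams,
    MembraneSpec,
    OperatingCondition,
    TimeSeries,
    estimate_conductance,
    estimate_fouling,
    feed_concentration_step,
    flux,
    generation_mass,
    lumped_conductance,
    mmhg_to_pa,
    simulate_iids,
)
from gutdial.transfer import UnstableStepError


class TestUnitsAndConductance:
    @pytest.mark.parametrize(
        "mmhg, pa", [(0.0, 0.0), (59.73, 7963.3), (-7.25, -966.6)]
    )
    def test_pressure_conversion(self, mmhg, pa):
        assert mmhg_to_pa(mmhg) == pytest.approx(pa, abs=0.05)

    def test_conductance_sum_and_components(self):
        mem = MembraneSpec(k=8e-4, area=1.0, k_uf=2e-4)
        c = lumped_conductance(mem, dp_pa=1.0)
        assert c.total == pytest.approx(1e-3)
        assert c.diffusive == pytest.approx(8e-4)
        assert c.convective == pytest.approx(2e-4)

    def test_pure_diffusion_when_no_ultrafiltration(self):
        mem = MembraneSpec(k=3e-4, area=1.7, k_uf=0.0)
        for dp in (-5000.0, 0.0, 5000.0):
            assert lumped_conductance(mem, dp).total == pytest.approx(3e-4 * 1.7)

    def test_negative_pressure_shrinks_conductance(self):
        mem = MembraneSpec(k=3e-4, area=1.7, k_uf=1e-8)
        assert lumped_conductance(mem, -966.6).total < mem.k * mem.area

    def test_negative_convection_clipping(self):
        mem = MembraneSpec(k=3e-4, area=1.7, k_uf=1e-8)
        clipped = lumped_conductance(mem, -966.6, clip_negative_convection=True)
        assert clipped.total == pytest.approx(mem.k * mem.area)
        assert clipped.convective == 0.0

    def test_invalid_regime_raises(self):
        mem = MembraneSpec(k=1e-6, area=1.0, k_uf=1e-6)
        with pytest.raises(InvalidRegimeError):
            lumped_conductance(mem, dp_pa=-10.0)

    def test_higher_pressure_higher_flux(self):
        # monotonicity sweep: for a fixed gradient, raising ΔP raises flux
        mem = MembraneSpec(k=3e-4, area=1.7, k_uf=1e-8)
        fluxes = [
            flux(lumped_conductance(mem, dp).total, 2.0, 500.0, 100.0)
            for dp in np.linspace(-900, 8000, 10)
        ]
        assert np.all(np.diff(fluxes) > 0)


class TestFlux:
    def test_zero_gradient(self):
        assert flux(1e-3, 1.0, 123.0, 123.0) == 0.0

    def test_arithmetic(self):
        assert flux(1e-3, 4.0, 300.0, 100.0) == pytest.approx(0.05)

    def test_doubling_resistance_halves_flux(self):
        assert flux(1e-3, 8.0, 300.0, 100.0) == pytest.approx(0.025)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        cf=st.floats(0, 1e4), cd=st.floats(0, 1e4),
        r=st.floats(0.1, 50), c=st.floats(1e-6, 1e-2),
    )
    def test_antisymmetry(self, cf, cd, r, c):
        assert flux(c, r, cf, cd) == pytest.approx(-flux(c, r, cd, cf), abs=1e-12)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError):
            flux(1e-3, 0.0, 1.0, 0.0)


class TestFeedConcentrationStep:
    @pytest.mark.parametrize(
        "d_rs, dt, c, r, cd, expected",
        [
            (0.1, 1.0, 1e-3, 1.0, 0.0, 100.0),
            (0.1, 1.0, 1e-3, 2.0, 0.0, 200.0),
            (0.0, 1.0, 1e-3, 1.0, 42.0, 42.0),
        ],
    )
    def test_arithmetic(self, d_rs, dt, c, r, cd, expected):
        assert feed_concentration_step(d_rs, dt, c, r, cd) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        d_rs=st.floats(0, 1.0), dt=st.floats(0.01, 5.0),
        c=st.floats(1e-6, 1e-2), cd=st.floats(0, 1e3),
    )
    def test_unit_resistance_reduces_to_plain_balance_bitwise(self, d_rs, dt, c, cd):
        # with R_MT = 1 the resistance form must equal the resistance-free
        # discretized balance bit for bit
        assert feed_concentration_step(d_rs, dt, c, 1.0, cd) == cd + (d_rs / dt) / c

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            feed_concentration_step(0.1, 0.0, 1e-3)
        with pytest.raises(ValueError):
            feed_concentration_step(0.1, 1.0, 0.0)


class TestFoulingProfile:
    def test_step_and_linear_interpolation(self):
        prof = FoulingProfile([10.0, 20.0], [2.0, 4.0], interpolation="step")
        assert prof.at(5.0) == 2.0  # before first knot: nearest interval value
        assert prof.at(15.0) == 4.0  # interval ending at 20
        assert prof.at(25.0) == 4.0
        lin = FoulingProfile([10.0, 20.0], [2.0, 4.0], interpolation="linear")
        assert lin.at(15.0) == pytest.approx(3.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            FoulingProfile([0.0, 1.0], [1.0, -2.0])
        with pytest.raises(ValueError):
            FoulingProfile([1.0, 1.0], [1.0, 1.0])


class TestSimulate:
    def test_zero_generation_stays_at_rest(self, simple_membrane, simple_condition):
        params = KineticParams(rs_inf=0.0, k=0.1)
        for mode in ("quasi_steady", "two_compartment"):
            s = simulate_iids(params, simple_membrane, simple_condition,
                              dt=0.5, horizon=30, mode=mode)
            assert np.all(s.cf == 0) and np.all(s.cd == 0)

    def test_closed_system_conservation(self, simple_membrane, simple_condition):
        params = KineticParams(rs_inf=5.0, k=0.05)
        s = simulate_iids(params, simple_membrane, simple_condition,
                          dt=0.1, horizon=60, mode="two_compartment")
        closure = s.feed_mass() + s.dialysate_mass() - generation_mass(params, s.times)
        assert np.abs(closure).max() < 1e-9

    def test_step_refinement(self, simple_membrane, simple_condition):
        params = KineticParams(rs_inf=5.0, k=0.05)
        out = {}
        for dt in (0.01, 0.0001):
            s = simulate_iids(params, simple_membrane, simple_condition,
                              dt=dt, horizon=60, mode="two_compartment")
            out[dt] = (s.cf[-1], s.cd[-1])
        assert out[0.01][0] == pytest.approx(out[0.0001][0], rel=1e-3)
        assert out[0.01][1] == pytest.approx(out[0.0001][1], rel=1e-3)

    def test_equilibration_after_generation_exhausted(self, simple_membrane, simple_condition):
        # fast generation, long run: the gradient decays monotonically to 0
        # and both tanks end at total mass / total volume
        params = KineticParams(rs_inf=5.0, k=0.5)
        s = simulate_iids(params, simple_membrane, simple_condition,
                          dt=0.1, horizon=400, mode="two_compartment")
        gap = s.cf - s.cd
        late = s.times > 20
        assert np.all(np.diff(gap[late]) <= 1e-12)
        c_eq = 5.0 / (2.0 + 20.0)  # g over total litres -> mg/mL
        assert s.cf[-1] == pytest.approx(c_eq, rel=1e-2)
        assert s.cd[-1] == pytest.approx(c_eq, rel=1e-2)

    def test_overflow_truncates(self, simple_condition):
        mem = MembraneSpec(k=1e-3, area=1.0, k_uf=2e-7)
        cond = OperatingCondition(q_feed=225, q_dial=386, dp_mmhg=-7.25,
                                  vf0_l=2.0, vd0_l=20.0, vf_cap_l=2.1)
        params = KineticParams(rs_inf=3.0, k=0.037)
        s = simulate_iids(params, mem, cond, dt=0.1, horizon=60,
                          mode="two_compartment")
        assert s.truncated
        assert s.times[-1] < 60
        assert s.vf[-1] >= 2.1 * (1 - 1e-9)

    def test_negative_volume_aborts(self):
        mem = MembraneSpec(k=1e-3, area=1.0, k_uf=1e-6)
        cond = OperatingCondition(q_feed=400, q_dial=250, dp_mmhg=59.73,
                                  vf0_l=2.0, vd0_l=20.0)
        with pytest.raises(ValueError, match="volume"):
            simulate_iids(KineticParams(5.0, 0.05), mem, cond,
                          dt=0.1, horizon=60, mode="two_compartment")

    def test_unstable_step_reported(self, simple_condition):
        mem = MembraneSpec(k=0.05, area=1.0, k_uf=0.0)  # very fast transfer
        with pytest.raises(UnstableStepError):
            simulate_iids(KineticParams(5.0, 0.05), mem, simple_condition,
                          dt=10.0, horizon=60, mode="two_compartment")


class TestEstimateFouling:
    def test_interval_arithmetic(self, simple_membrane, simple_condition):
        # gradient 100 g/m³ (0.1 mg/mL), generation 0.05 g/min, c = 1e-3
        # -> R_MT = 100·1e-3/0.05 = 2
        params = KineticParams(rs_inf=1e6, k=5e-8)  # near-linear: rate ~0.05 g/min
        t = np.array([0.0, 1.0])
        d_rs = generation_mass(params, 1.0)
        series = TimeSeries(t, [0.0, 0.1], [0.0, 0.0], [2.0, 2.0], [20.0, 20.0])
        est = estimate_fouling(series, params, simple_membrane, simple_condition)
        assert est.r_mt[0] == pytest.approx(100.0 * 1e-3 / d_rs, rel=1e-9)
        assert est.r_mt[0] == pytest.approx(2.0, rel=1e-3)

    def test_round_trip_piecewise_constant(self, simple_membrane, simple_condition):
        params = KineticParams(rs_inf=5.0, k=0.05)
        prof = FoulingProfile([0.0, 20.0, 40.0], [3.0, 5.0, 2.0], interpolation="step")
        s = simulate_iids(params, simple_membrane, simple_condition,
                          fouling=prof, dt=0.5, horizon=60, mode="quasi_steady")
        est = estimate_fouling(s, params, simple_membrane, simple_condition)
        truth = np.atleast_1d(prof.at(est.times))
        ok = est.defined & ~est.degenerate
        assert ok.all()
        np.testing.assert_allclose(est.r_mt[ok], truth[ok], rtol=0.01)

    def test_constant_resistance_round_trip(self, simple_membrane, simple_condition):
        params = KineticParams(rs_inf=5.0, k=0.05)
        s = simulate_iids(params, simple_membrane, simple_condition,
                          fouling=FoulingProfile.constant(3.0),
                          dt=0.5, horizon=60, mode="quasi_steady")
        est = estimate_fouling(s, params, simple_membrane, simple_condition)
        np.testing.assert_allclose(est.r_mt[est.defined], 3.0, rtol=0.01)

    def test_zero_gradient_flagged_degenerate(self, simple_membrane, simple_condition):
        params = KineticParams(rs_inf=5.0, k=0.05)
        t = np.arange(0.0, 20.0, 2.0)
        series = TimeSeries(t, np.full_like(t, 0.3), np.full_like(t, 0.3),
                            np.full_like(t, 2.0), np.full_like(t, 20.0))
        est = estimate_fouling(series, params, simple_membrane, simple_condition)
        assert est.defined.all()
        assert est.degenerate.all()
        np.testing.assert_allclose(est.r_mt, 0.0, atol=1e-12)

    def test_exhausted_generation_flagged_undefined(self, simple_membrane, simple_condition):
        # far beyond the plateau the per-interval generation increment
        # vanishes and the resistance is indeterminate, not infinite
        params = KineticParams(rs_inf=1.0, k=0.5)
        t = np.array([0.0, 100.0, 200.0])
        series = TimeSeries(t, [0.0, 0.2, 0.1], [0.0, 0.0, 0.0],
                            [2.0] * 3, [20.0] * 3)
        est = estimate_fouling(series, params, simple_membrane, simple_condition)
        assert not est.defined[-1]
        assert np.isnan(est.r_mt[-1])


class TestEstimateConductance:
    @staticmethod
    def _synthetic_run(c=1e-3, vf_m3=2e-3, c0=10.0, cd0=0.0):
        t = np.arange(1.0, 31.0)
        cd = np.full_like(t, cd0)
        cf = cd + (c0 - cd0) * np.exp(-c * t / vf_m3)
        series = TimeSeries(t, cf, cd if cd0 else np.zeros_like(t),
                            np.full_like(t, 2.0), np.full_like(t, 20.0))
        return CalibrationRun(series, c0)

    def test_round_trip(self):
        res = estimate_conductance(self._synthetic_run(), vf_m3=2e-3)
        assert res.conductance == pytest.approx(1e-3, rel=1e-6)
        assert not res.fouling_suspected

    def test_half_life_closed_form(self):
        res = estimate_conductance(self._synthetic_run(), vf_m3=2e-3)
        assert res.half_life_min == pytest.approx(2e-3 * np.log(2) / 1e-3, rel=1e-6)

    def test_zero_driving_force_rejected(self):
        t = np.arange(1.0, 10.0)
        series = TimeSeries(t, np.full_like(t, 0.5), np.full_like(t, 0.5) - 1e-9,
                            np.full_like(t, 2.0), np.full_like(t, 20.0))
        with pytest.raises(ValueError):
            estimate_conductance(CalibrationRun(series, 0.5 - 1e-9), 2e-3)

    def test_summary_reports_conductance(self):
        text = estimate_conductance(self._synthetic_run(), vf_m3=2e-3).summary()
        assert "c (m^3/min)" in text and "0.001" in text


class TestTimeSeriesValidation:
    def test_rejects_bad_series(self):
        with pytest.raises(ValueError):
            TimeSeries([0.0, 1.0, 1.0], [0, 0, 0], [0, 0, 0], [1, 1, 1], [1, 1, 1])
        with pytest.raises(ValueError):
            TimeSeries([0.0, 1.0], [0, -0.1], [0, 0], [1, 1], [1, 1])
        with pytest.raises(ValueError):
            TimeSeries([0.0, 1.0], [0, 0.1], [0, 0], [1, 0], [1, 1])
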
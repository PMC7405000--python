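"""Dialysis mass transfer between the feed (lumen) and dialysate compartments.

The bench system couples a stirred feed tank, in which gelatinized
starch is being hydrolysed, to a hollow-fiber dialysis module.  Solute
crosses the membrane by diffusion (driven by the concentration gradient)
and by convection (driven by the transmembrane pressure ΔP).  Both
effects are lumped into a single volumetric conductance

    c = K·A_T + K_UF·ΔP        [m³/min]

with K the overall mass-transfer coefficient (m/min), A_T the transfer
area (m²) and K_UF the ultrafiltration coefficient (m³/(Pa·min)).  A
dimensionless, time-varying fouling resistance R_MT attenuates the flux:

    N_rs = (c / R_MT) · (C_F − C_D)        [g/min]

Two forward schemes are provided.  The quasi-steady scheme equates the
instantaneous transferred mass to the instantaneous generated mass and
solves algebraically for the feed concentration; the two-compartment
scheme integrates the explicit accumulation balance in both tanks,
including the ultrafiltration water flux that drifts the feed volume.
The inverse problems — estimating c from a pure-solute calibration run
and estimating R_MT(t) from a digestion run — are also here.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .kinetics import KineticParams, generation_mass
from .units import (
    g_m3_to_mg_ml,
    litres_to_m3,
    m3_to_litres,
    mg_ml_to_g_m3,
    mmhg_to_pa,
    pa_to_mmhg,
)

__all__ = [
    "MembraneSpec",
    "OperatingCondition",
    "TimeSeries",
    "FoulingProfile",
    "FoulingEstimate",
    "CalibrationRun",
    "Conductance",
    "InvalidRegimeError",
    "UnstableStepError",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "lumped_conductance",
    "flux",
    "feed_concentration_step",
    "simulate_iids",
    "estimate_fouling",
    "estimate_conductance",
    "ConductanceCalibration",
    "ConductanceCalibrationResults",
]


class InvalidRegimeError(ValueError):
    """Raised when a strongly negative ΔP overwhelms diffusive transfer."""


class UnstableStepError(RuntimeError):
    """Raised when the explicit time step is too coarse for the transfer rate."""


@dataclass(frozen=True)
class MembraneSpec:
    """Constants of a hollow-fiber dialysis module.

    ``k`` is the overall mass transfer coefficient (m/min), ``area`` the
    total transfer area A_T (m²) and ``k_uf`` the ultrafiltration
    coefficient (m³/(Pa·min)).  ``mwco_kda`` is metadata only: the
    molecular-weight cut-off limits which hydrolysis products can cross
    at all, but it does not enter the lumped model.
    """

    k: float
    area: float
    k_uf: float = 0.0
    mwco_kda: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"K must be > 0, got {self.k}")
        if not self.area > 0:
            raise ValueError(f"A_T must be > 0, got {self.area}")
        if self.k_uf < 0:
            raise ValueError(f"K_UF must be >= 0, got {self.k_uf}")


@dataclass(frozen=True)
class OperatingCondition:
    """Run settings: flows, transmembrane pressure and tank volumes.

    Flows are recorded in mL/min (they label the operating point; the
    lumped model sees them only through ΔP).  ``dp_mmhg`` is signed:
    positive pressure pushes water from feed to dialysate.  Volumes in
    litres; ``vf_cap_l`` is the feed-tank capacity at which the run must
    stop (overflow).
    """

    q_feed: float
    q_dial: float
    dp_mmhg: float
    vf0_l: float
    vd0_l: float
    vf_cap_l: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.q_feed > 0 or not self.q_dial > 0:
            raise ValueError("flows must be > 0")
        if not self.vf0_l > 0 or not self.vd0_l > 0:
            raise ValueError("initial volumes must be > 0")
        if self.vf_cap_l is not None and self.vf_cap_l <= self.vf0_l:
            raise ValueError("vf_cap_l must exceed the initial feed volume")

    @property
    def dp_pa(self) -> float:
        return mmhg_to_pa(self.dp_mmhg)


@dataclass
class TimeSeries:
    """Sampled feed/dialysate concentrations and tank volumes over a run.

    Concentrations in mg glucose-equivalent per mL, volumes in litres.
    ``truncated`` marks a run stopped early (feed-tank overflow).
    """

    times: np.ndarray
    cf: np.ndarray
    cd: np.ndarray
    vf: np.ndarray
    vd: np.ndarray
    truncated: bool = False

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("times", "cf", "cd", "vf", "vd"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arrays[name])
        n = arrays["times"].size
        if any(a.ndim != 1 or a.size != n for a in arrays.values()):
            raise ValueError("all series columns must be 1-D of equal length")
        if np.any(np.diff(arrays["times"]) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(arrays["cf"] < 0) or np.any(arrays["cd"] < 0):
            raise ValueError("concentrations must be >= 0")
        if np.any(arrays["vf"] <= 0) or np.any(arrays["vd"] <= 0):
            raise ValueError("volumes must be > 0")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times,
                "cf_mg_ml": self.cf,
                "cd_mg_ml": self.cd,
                "vf_ml": self.vf * 1000.0,
                "vd_ml": self.vd * 1000.0,
            }
        )

    def feed_mass(self) -> np.ndarray:
        """Reducing-sugar mass in the feed tank over time (g)."""
        return self.cf * self.vf

    def dialysate_mass(self) -> np.ndarray:
        """Reducing-sugar mass in the dialysate tank over time (g)."""
        return self.cd * self.vd


@dataclass
class FoulingProfile:
    """Time-indexed dimensionless mass-transfer resistance R_MT.

    ``interpolation`` selects how values between knots are read:
    ``"step"`` holds the value of the next knot at or after t (matching
    the per-interval semantics of the discretized balance), ``"linear"``
    interpolates.  Outside the knot range the nearest value is held.
    """

    times: np.ndarray
    r_mt: np.ndarray
    interpolation: str = "step"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.r_mt, dtype=float)
        self.times, self.r_mt = t, r
        if t.ndim != 1 or r.ndim != 1 or t.size != r.size or t.size == 0:
            raise ValueError("times and r_mt must be nonempty 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~(r > 0)):
            raise ValueError("R_MT must be > 0 everywhere")
        if self.interpolation not in ("step", "linear"):
            raise ValueError(f"unknown interpolation rule {self.interpolation!r}")

    @classmethod
    def constant(cls, value: float) -> "FoulingProfile":
        return cls(np.array([0.0]), np.array([float(value)]), interpolation="step")

    def at(self, t):
        """Resistance value(s) at time(s) ``t``."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.interpolation == "linear":
            out = np.interp(t, self.times, self.r_mt)
        else:
            # hold the value of the knot ending the interval containing t
            idx = np.searchsorted(self.times, t, side="left")
            idx = np.clip(idx, 0, self.times.size - 1)
            out = self.r_mt[idx]
        return out if out.size > 1 else float(out[0])


@dataclass(frozen=True)
class CalibrationRun:
    """A pure-solute (no generation) run used to calibrate conductance.

    ``c0_mg_ml`` is the initial feed concentration.  With no reaction the
    gradient decays exponentially, ln((C_F−C_D)/(C_0−C_D)) = −c·t/V_F,
    which identifies the lumped conductance c from the slope.
    """

    series: TimeSeries
    c0_mg_ml: float

    def __post_init__(self) -> None:
        if not self.c0_mg_ml > 0:
            raise ValueError("initial feed concentration must be > 0")


class Conductance(NamedTuple):
    """Lumped volumetric conductance and its two components (m³/min)."""

    total: float
    diffusive: float
    convective: float


def lumped_conductance(
    membrane: MembraneSpec,
    dp_pa: float,
    clip_negative_convection: bool = False,
) -> Conductance:
    """Lumped conductance c = K·A_T + K_UF·ΔP with its components.

    The diffusive component K·A_T and the convective component K_UF·ΔP
    are the per-area diffusive and convective fluxes once multiplied by
    the concentration gradient.  A negative ΔP (water entering the feed)
    reduces c; if it drives c ≤ 0 the lumped model has no valid regime
    and :class:`InvalidRegimeError` is raised.  With
    ``clip_negative_convection`` the convective term is floored at zero
    for ΔP < 0 (water entering the feed then carries no solute out).
    """
    diffusive = membrane.k * membrane.area
    convective = membrane.k_uf * dp_pa
    if clip_negative_convection and convective < 0:
        convective = 0.0
    total = diffusive + convective
    if total <= 0:
        raise InvalidRegimeError(
            f"lumped conductance {total:.3g} m³/min <= 0: negative transmembrane "
            "pressure overwhelms diffusive transfer"
        )
    return Conductance(total=total, diffusive=diffusive, convective=convective)


def flux(c: float, r_mt: float, cf: float, cd: float) -> float:
    """Membrane mass flux N_rs = (c/R_MT)·(C_F − C_D) in g/min.

    ``c`` in m³/min, concentrations in g/m³.  Antisymmetric in
    (cf, cd); zero when the compartments are at the same concentration.
    """
    if not r_mt > 0:
        raise ValueError(f"R_MT must be > 0, got {r_mt}")
    return c / r_mt * (cf - cd)


def feed_concentration_step(
    d_rs: float, dt: float, c: float, r_mt: float = 1.0, cd: float = 0.0
) -> float:
    """Quasi-steady feed concentration for one interval (g/m³).

    Solves (d_rs/dt) = (c/R_MT)·(C_F − C_D) for C_F: the feed
    concentration that makes the membrane carry exactly the mass
    generated over the interval.  With ``r_mt = 1`` this reduces exactly
    to the resistance-free balance.
    """
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if not c > 0:
        raise ValueError(f"conductance must be > 0, got {c}")
    if not r_mt > 0:
        raise ValueError(f"R_MT must be > 0, got {r_mt}")
    return cd + (d_rs / dt) * r_mt / c


def simulate_iids(
    params: KineticParams,
    membrane: MembraneSpec,
    condition: OperatingCondition,
    fouling: Optional[FoulingProfile] = None,
    dt: float = 0.1,
    horizon: float = 60.0,
    mode: str = "two_compartment",
    clip_negative_convection: bool = False,
) -> TimeSeries:
    """Forward-simulate a coupled digestion/dialysis run.

    Parameters
    ----------
    params, membrane, condition
        Generation kinetics, membrane constants and run settings.
    fouling
        Resistance profile R_MT(t); defaults to the clean membrane
        (R_MT = 1).
    dt, horizon
        Explicit time step and run length, min.
    mode
        ``"quasi_steady"``: per interval, all generated mass is
        transferred and the feed concentration follows algebraically;
        volumes stay constant.  ``"two_compartment"``: explicit Euler
        integration of the accumulation balances dM_F/dt = gen − N_rs,
        dM_D/dt = N_rs, with the water flux K_UF·ΔP drifting the
        volumes; the generation increment per step is taken from the
        closed-form kinetics (exact), only the transfer term is
        discretized.  Stops early, with ``truncated=True``, if the feed
        volume reaches the overflow capacity.

    Returns
    -------
    TimeSeries on the grid 0, dt, 2·dt, … (mg/mL, litres).
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if horizon < dt:
        raise ValueError("horizon must be at least one step")
    if mode not in ("quasi_steady", "two_compartment"):
        raise ValueError(f"unknown mode {mode!r}")
    if fouling is None:
        fouling = FoulingProfile.constant(1.0)

    cond = lumped_conductance(membrane, condition.dp_pa, clip_negative_convection)
    c = cond.total
    n_steps = int(round(horizon / dt))
    times = np.arange(n_steps + 1) * dt
    vf0 = litres_to_m3(condition.vf0_l)
    vd0 = litres_to_m3(condition.vd0_l)
    gen = generation_mass(params, times)

    cf = np.zeros(n_steps + 1)
    cd = np.zeros(n_steps + 1)
    vf = np.full(n_steps + 1, vf0)
    vd = np.full(n_steps + 1, vd0)
    truncated = False
    end = n_steps
    r_vals = np.atleast_1d(fouling.at(times))

    if mode == "quasi_steady":
        # all generated mass crosses instantly; C_F follows from the gradient
        # the membrane needs to carry it
        m_d = 0.0
        for i in range(1, n_steps + 1):
            d_rs = gen[i] - gen[i - 1]
            m_d += d_rs
            cd[i] = m_d / vd0
            cf[i] = feed_concentration_step(d_rs, dt, c, r_vals[i], cd[i])
    else:
        r_min = float(r_vals.min())
        water_flux = membrane.k_uf * condition.dp_pa  # m³/min, feed → dialysate
        # explicit-Euler stability: per-step transferred fraction of the
        # gradient must stay below 1 in each compartment
        if c * dt / r_min * (1.0 / vf0 + 1.0 / vd0) > 1.0:
            raise UnstableStepError(
                "time step too coarse for the transfer rate; reduce dt"
            )
        m_f = m_d = 0.0
        v_f, v_d = vf0, vd0
        cap_m3 = litres_to_m3(condition.vf_cap_l) if condition.vf_cap_l else None
        for i in range(1, n_steps + 1):
            n_rs = flux(c, r_vals[i], m_f / v_f, m_d / v_d)
            m_f += (gen[i] - gen[i - 1]) - n_rs * dt
            m_d += n_rs * dt
            v_f -= water_flux * dt
            v_d += water_flux * dt
            if v_f <= 0 or v_d <= 0:
                raise ValueError(
                    f"compartment volume became nonpositive at t={times[i]:g} min; "
                    "check K_UF, ΔP and the horizon"
                )
            m_f = max(m_f, 0.0)
            cf[i], cd[i] = m_f / v_f, m_d / v_d
            vf[i], vd[i] = v_f, v_d
            if cap_m3 is not None and v_f >= cap_m3 * (1 - 1e-12):
                truncated = True
                end = i
                break

    sl = slice(0, end + 1)
    return TimeSeries(
        times=times[sl],
        cf=g_m3_to_mg_ml(cf[sl]),
        cd=g_m3_to_mg_ml(cd[sl]),
        vf=m3_to_litres(vf[sl]),
        vd=m3_to_litres(vd[sl]),
        truncated=truncated,
    )


@dataclass
class FoulingEstimate:
    """Per-interval fouling resistance estimated from a run.

    ``r_mt`` holds one value per sampling interval, indexed by the
    interval's right endpoint; NaN where the generation increment over
    the interval was below tolerance (resistance indeterminate).
    ``defined`` marks intervals with a usable estimate; ``degenerate``
    marks defined intervals whose estimate is not positive (e.g. zero
    gradient despite positive generation).
    """

    times: np.ndarray
    r_mt: np.ndarray
    defined: np.ndarray
    degenerate: np.ndarray

    def profile(self, interpolation: str = "step") -> FoulingProfile:
        """Usable (defined, positive) estimates as a FoulingProfile."""
        ok = self.defined & ~self.degenerate
        if not ok.any():
            raise ValueError("no usable fouling estimates in this run")
        return FoulingProfile(self.times[ok], self.r_mt[ok], interpolation=interpolation)


def estimate_fouling(
    series: TimeSeries,
    params: KineticParams,
    membrane: MembraneSpec,
    condition: OperatingCondition,
    clip_negative_convection: bool = False,
    gen_tol: float = 1e-9,
) -> FoulingEstimate:
    """Estimate R_MT per sampling interval by inverting the quasi-steady balance.

    For the interval ending at t_i,

        R_MT = (C_F − C_D)·Δt·(K·A_T + K_UF·ΔP) / (rs_{t_i} − rs_{t_{i−1}})

    with the generation increment taken from the closed-form kinetics.
    Intervals whose generation increment falls below ``gen_tol`` (g) are
    flagged indeterminate rather than silently dropped.
    """
    if len(series) < 2:
        raise ValueError("need at least two samples to estimate fouling")
    c = lumped_conductance(membrane, condition.dp_pa, clip_negative_convection).total
    t = series.times
    gen = generation_mass(params, t)
    d_rs = np.diff(gen)
    dt = np.diff(t)
    grad = mg_ml_to_g_m3(series.cf[1:] - series.cd[1:])
    defined = d_rs > gen_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(defined, grad * dt * c / d_rs, np.nan)
    degenerate = defined & ~(r > 0)
    return FoulingEstimate(times=t[1:], r_mt=r, defined=defined, degenerate=degenerate)


class ConductanceCalibration:
    """Log-linear calibration of the lumped conductance from a pure-solute run.

    With no generation the transfer balance integrates to
    ln((C_F − C_D)/(C_0 − C_D)) = −c·t/V_F; a straight-line fit of the
    left side against time identifies c = −slope·V_F.
    """

    def __init__(self, run: CalibrationRun, vf_m3: float):
        if not vf_m3 > 0:
            raise ValueError("feed volume must be > 0")
        s = run.series
        if np.any(s.cf <= s.cd):
            raise ValueError("calibration requires cf > cd throughout the run")
        if abs(run.c0_mg_ml - s.cd[0]) <= 0:
            raise ValueError("zero driving force: c0 equals the dialysate concentration")
        self.run = run
        self.vf_m3 = vf_m3

    def fit(self) -> "ConductanceCalibrationResults":
        s = self.run.series
        c0 = mg_ml_to_g_m3(self.run.c0_mg_ml)
        cf = mg_ml_to_g_m3(s.cf)
        cd = mg_ml_to_g_m3(s.cd)
        denom = c0 - cd
        if np.any(denom <= 0):
            raise ValueError("zero or negative driving force: c0 <= cd")
        y = np.log((cf - cd) / denom)
        reg = stats.linregress(s.times, y)
        resid = y - (reg.intercept + reg.slope * s.times)
        # curvature check: a quadratic term picking up systematic residual
        # structure suggests time-varying resistance (fouling)
        if s.times.size >= 4:
            quad = np.polyfit(s.times, resid, 2)[0]
            scale = np.std(y) / max(s.times[-1] ** 2, 1e-12)
            fouling_suspected = abs(quad) > 0.05 * scale if scale > 0 else False
        else:
            fouling_suspected = False
        return ConductanceCalibrationResults(
            model=self,
            conductance=-reg.slope * self.vf_m3,
            slope=float(reg.slope),
            intercept=float(reg.intercept),
            rvalue=float(reg.rvalue),
            stderr=float(reg.stderr) * self.vf_m3,
            resid=resid,
            fouling_suspected=bool(fouling_suspected),
        )


@dataclass
class ConductanceCalibrationResults:
    """Calibrated conductance c (m³/min) with regression diagnostics."""

    model: ConductanceCalibration
    conductance: float
    slope: float
    intercept: float
    rvalue: float
    stderr: float
    resid: np.ndarray = field(repr=False)
    fouling_suspected: bool = False

    @property
    def half_life_min(self) -> float:
        """Time for the gradient to halve: V_F·ln2/c."""
        return self.model.vf_m3 * math.log(2.0) / self.conductance

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Lumped-conductance calibration (log-linear)\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"{'c (m^3/min)':<22}{self.conductance:>24.6g}\n")
        buf.write(f"{'std err':<22}{self.stderr:>24.3g}\n")
        buf.write(f"{'r':<22}{self.rvalue:>24.5f}\n")
        buf.write(f"{'gradient half-life':<22}{self.half_life_min:>20.3g} min\n")
        buf.write(f"{'fouling suspected':<22}{str(self.fouling_suspected):>24}\n")
        return buf.getvalue()


def estimate_conductance(run: CalibrationRun, vf_m3: float) -> ConductanceCalibrationResults:
    """Fit the log-linear transfer relation; returns results with ``.conductance``."""
    return ConductanceCalibration(run, vf_m3).fit()
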
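import numpy as np
import pytest

from gutdial import KineticParams, MembraneSpec, OperatingCondition


@pytest.fixture
def batch_params():
    """Batch digestion kinetics: 6.7 g plateau, 0.037 1/min, 20 g starch."""
    return KineticParams(rs_inf=6.7, k=0.037, m0=20.0)


@pytest.fixture
def simple_membrane():
    """Round-number membrane: c = K·A_T = 1e-3 m³/min, no ultrafiltration."""
    return MembraneSpec(k=1e-3, area=1.0, k_uf=0.0)


@pytest.fixture
def simple_condition():
    """2 L feed, 20 L dialysate, no transmembrane pressure."""
    return OperatingCondition(q_feed=400.0, q_dial=400.0, dp_mmhg=0.0,
                              vf0_l=2.0, vd0_l=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
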
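"""Unit conversions used at the I/O boundaries.

All internal computation is carried out in a single consistent system:
mass in g, volume in m³, pressure in Pa, time in min, concentration in
g/m³.  Bench instruments and the literature report transmembrane
pressure in mmHg, concentration in mg glucose-equivalent per mL
(numerically equal to g/L) and tank volumes in mL or L, so conversions
live here and nowhere else.
"""

from __future__ import annotations

#: Pascals per millimetre of mercury (conventional value).
PA_PER_MMHG: float = 133.322

#: g/m³ per mg/mL (mg/mL ≡ g/L ≡ 1000 g/m³).
G_PER_M3_PER_MG_PER_ML: float = 1000.0

#: m³ per litre.
M3_PER_L: float = 1e-3


def mmhg_to_pa(dp_mmhg: float) -> float:
    """Convert a (signed) transmembrane pressure from mmHg to Pa."""
    return dp_mmhg * PA_PER_MMHG


def pa_to_mmhg(dp_pa: float) -> float:
    """Inverse of :func:`mmhg_to_pa`."""
    return dp_pa / PA_PER_MMHG


def mg_ml_to_g_m3(conc):
    """Concentration mg/mL → g/m³ (works on scalars and arrays)."""
    return conc * G_PER_M3_PER_MG_PER_ML


def g_m3_to_mg_ml(conc):
    """Concentration g/m³ → mg/mL (works on scalars and arrays)."""
    return conc / G_PER_M3_PER_MG_PER_ML


def litres_to_m3(volume_l):
    """Volume L → m³ (works on scalars and arrays)."""
    return volume_l * M3_PER_L


def m3_to_litres(volume_m3):
    """Volume m³ → L (works on scalars and arrays)."""
    return volume_m3 / M3_PER_L
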
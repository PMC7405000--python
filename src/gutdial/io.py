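"""Delimited-text readers/writers and run configuration.

CSV dialect: comma separator, dot decimal, UTF-8, one mandatory header
line, optional ``#``-prefixed metadata lines before the header.  Run
series use columns ``time_min, cf_mg_ml, cd_mg_ml, vf_ml, vd_ml``;
batch curves use ``time_min, rs_g``; fouling profiles use
``time_min, r_mt``.  Numbers are written with 12 significant digits so
a write→read round trip is lossless at that precision.

The run configuration is a YAML file with blocks ``membrane``,
``condition``, ``kinetics``, ``simulation`` and optionally
``reference``; unknown keys anywhere are rejected so that typos fail
loudly instead of silently falling back to defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .kinetics import BatchCurve, KineticParams
from .scaleup import IntestineReference
from .transfer import FoulingProfile, MembraneSpec, OperatingCondition, TimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_batch_curve",
    "write_batch_curve",
    "read_fouling_profile",
    "write_fouling_profile",
    "RunConfig",
    "SimulationSettings",
    "load_config",
]

_FLOAT_FMT = "%.12g"


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    return meta


def write_timeseries(series: TimeSeries, path) -> None:
    """Write a run series; the truncated flag goes into a metadata comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# truncated: {str(series.truncated).lower()}\n")
        series.to_frame().to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_timeseries(path, default_vf_ml: float = 2000.0, default_vd_ml: float = 20000.0) -> TimeSeries:
    """Read a run series written by :func:`write_timeseries`.

    Files lacking the volume columns are accepted with a constant-volume
    fallback (defaults 2000/20000 mL, the standard tank fills) and a
    warning.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    required = {"time_min", "cf_mg_ml", "cd_mg_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    n = len(df)
    if "vf_ml" in df.columns and "vd_ml" in df.columns:
        vf_ml = df["vf_ml"].to_numpy(float)
        vd_ml = df["vd_ml"].to_numpy(float)
    else:
        warnings.warn(
            f"{path}: no volume columns; assuming constant volumes "
            f"{default_vf_ml:g}/{default_vd_ml:g} mL", stacklevel=2,
        )
        vf_ml = np.full(n, default_vf_ml)
        vd_ml = np.full(n, default_vd_ml)
    return TimeSeries(
        times=df["time_min"].to_numpy(float),
        cf=df["cf_mg_ml"].to_numpy(float),
        cd=df["cd_mg_ml"].to_numpy(float),
        vf=vf_ml / 1000.0,
        vd=vd_ml / 1000.0,
        truncated=meta.get("truncated", "false") == "true",
    )


def write_batch_curve(curve: BatchCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_batch_curve(path) -> BatchCurve:
    df = pd.read_csv(path, comment="#")
    missing = {"time_min", "rs_g"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return BatchCurve.from_frame(df)


def write_fouling_profile(profile: FoulingProfile, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# interpolation: {profile.interpolation}\n")
        pd.DataFrame({"time_min": profile.times, "r_mt": profile.r_mt}).to_csv(
            fh, index=False, float_format=_FLOAT_FMT
        )


def read_fouling_profile(path) -> FoulingProfile:
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#")
    missing = {"time_min", "r_mt"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return FoulingProfile(
        df["time_min"].to_numpy(float),
        df["r_mt"].to_numpy(float),
        interpolation=meta.get("interpolation", "step"),
    )


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings of a forward run."""

    dt: float = 0.1
    horizon: float = 60.0
    mode: str = "two_compartment"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.horizon < self.dt:
            raise ValueError("horizon must be at least one step")
        if self.mode not in ("quasi_steady", "two_compartment"):
            raise ValueError(f"unknown simulation mode {self.mode!r}")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    membrane: MembraneSpec
    condition: OperatingCondition
    kinetics: KineticParams
    simulation: SimulationSettings
    reference: Optional[IntestineReference] = None


_BLOCK_KEYS = {
    "membrane": {"k", "area", "k_uf", "mwco_kda"},
    "condition": {"q_feed", "q_dial", "dp_mmhg", "vf0_l", "vd0_l", "vf_cap_l"},
    "kinetics": {"rs_inf", "k", "m0"},
    "simulation": {"dt", "horizon", "mode", "seed"},
    "reference": {
        "transfer_fraction", "volume_l", "area_m2", "feed_flow_ml_min",
        "digestion_time_min", "starch_conc0_mg_ml",
    },
}


def _check_block(name: str, block: dict) -> dict:
    if not isinstance(block, dict):
        raise ValueError(f"config block {name!r} must be a mapping")
    unknown = set(block) - _BLOCK_KEYS[name]
    if unknown:
        raise ValueError(f"unknown keys in config block {name!r}: {sorted(unknown)}")
    return block


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Required blocks: membrane (K m/min, area m², K_UF m³/(Pa·min)),
    condition (flows mL/min, dp_mmhg, volumes L), kinetics (rs_inf g,
    k 1/min, m0 g), simulation (dt/horizon min, mode, seed).  Optional:
    reference (human-intestine values for scale-up).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of blocks")
    unknown = set(raw) - set(_BLOCK_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown config blocks {sorted(unknown)}")
    for name in ("membrane", "condition", "kinetics", "simulation"):
        if name not in raw:
            raise ValueError(f"{path}: missing config block {name!r}")
    membrane = MembraneSpec(**_check_block("membrane", raw["membrane"]))
    condition = OperatingCondition(**_check_block("condition", raw["condition"]))
    kin = KineticParams(**_check_block("kinetics", raw["kinetics"]))
    sim = SimulationSettings(**_check_block("simulation", raw["simulation"]))
    ref = None
    if "reference" in raw:
        ref = IntestineReference(**_check_block("reference", raw["reference"]))
    return RunConfig(membrane=membrane, condition=condition, kinetics=kin,
                     simulation=sim, reference=ref)
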
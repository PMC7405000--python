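"""Efficiency summaries of a digestion/absorption run.

Three percentages characterise a run:

* starch digested — total reducing-sugar mass generated relative to the
  initial starch load, 100·rs/M0;
* membrane efficiency — the share of the generated mass that ended up on
  the dialysate side, 100·M_rsD/(M_rsF + M_rsD);
* expected overall efficiency — the dialysate mass relative to the
  maximum the batch digestion can produce, 100·M_rsD/M_T.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .kinetics import KineticParams, generation_mass
from .transfer import TimeSeries

__all__ = [
    "RunSummary",
    "membrane_efficiency",
    "expected_overall_efficiency",
    "starch_digested_percent",
    "summarize_run",
]


def membrane_efficiency(m_rs_dial: float, m_rs_feed: float) -> float:
    """Share of generated reducing sugars that crossed the membrane (%)."""
    if m_rs_dial < 0 or m_rs_feed < 0:
        raise ValueError("masses must be >= 0")
    total = m_rs_dial + m_rs_feed
    if not total > 0:
        raise ValueError("both compartment masses are zero; efficiency undefined")
    return 100.0 * m_rs_dial / total


def expected_overall_efficiency(m_rs_dial: float, m_t_batch: float) -> float:
    """Dialysate mass relative to the batch-digestion maximum (%)."""
    if not m_t_batch > 0:
        raise ValueError("batch maximum mass must be > 0")
    if m_rs_dial < 0:
        raise ValueError("dialysate mass must be >= 0")
    return 100.0 * m_rs_dial / m_t_batch


def starch_digested_percent(total_generated: float, m0: float) -> float:
    """Generated reducing-sugar mass relative to the starch load (%)."""
    if not m0 > 0:
        raise ValueError("initial starch mass must be > 0")
    if total_generated < 0:
        raise ValueError("generated mass must be >= 0")
    return 100.0 * total_generated / m0


@dataclass(frozen=True)
class RunSummary:
    """Final-state masses of a run plus the derived percentages."""

    total_generated: float
    m_rs_feed: float
    m_rs_dial: float
    m_t_batch: float
    m0: float

    def __post_init__(self) -> None:
        for name in ("total_generated", "m_rs_feed", "m_rs_dial", "m_t_batch", "m0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def membrane_efficiency_pct(self) -> float:
        return membrane_efficiency(self.m_rs_dial, self.m_rs_feed)

    @property
    def expected_overall_efficiency_pct(self) -> float:
        return expected_overall_efficiency(self.m_rs_dial, self.m_t_batch)

    @property
    def starch_digested_pct(self) -> float:
        return starch_digested_percent(self.total_generated, self.m0)

    def record(self, flow_ratio: str = "") -> dict:
        """One summary-table row (percentages as floats)."""
        return {
            "flow_ratio": flow_ratio,
            "starch_digested_pct": self.starch_digested_pct,
            "membrane_eff_pct": self.membrane_efficiency_pct,
            "expected_overall_eff_pct": self.expected_overall_efficiency_pct,
        }


def summarize_run(
    series: TimeSeries,
    params: KineticParams,
    batch_max: float,
    m0: float,
    flow_ratio: str = "",
) -> tuple[RunSummary, pd.DataFrame]:
    """Aggregate a run into final-point masses and the efficiency table row.

    Final masses are concentration × volume at the last sample
    (mg/mL × L = g); the total generated mass is the closed-form
    kinetics evaluated at the final time.
    """
    if len(series) == 0:
        raise ValueError("series is empty")
    t_end = float(series.times[-1])
    summary = RunSummary(
        total_generated=float(generation_mass(params, t_end)),
        m_rs_feed=float(series.cf[-1] * series.vf[-1]),
        m_rs_dial=float(series.cd[-1] * series.vd[-1]),
        m_t_batch=batch_max,
        m0=m0,
    )
    return summary, pd.DataFrame([summary.record(flow_ratio)])
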
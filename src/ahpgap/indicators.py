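"""Sub-criterion indicator models and alternative local weights.

Each sub-criterion leaf of the assessment hierarchy is backed by a simple
operational model: window sums of exam counts (executed exams, faults,
refusals...), ratios of financial aggregates (ROS = net operating margin /
net revenues), staffing totals, or expert score sums (technological safety
and legal compliance, each variable scored 1-10).  Computing the model for
every alternative over the same observation window and normalizing across
alternatives yields the alternatives' local weights at that leaf.

Indicators carry an orientation: *benefit* (larger is better — e.g.
effectiveness) or *cost* (larger is worse — e.g. faults queued, side
effects).  Cost-type values are inverted before normalization so that a
larger weight always means a more preferred alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "TIMESTEP_COLUMNS",
    "ORIENTATION",
    "ScorePanel",
    "IndicatorPanel",
    "compute_indicator_panel",
    "local_alternative_weights",
    "panel_local_weights",
]

#: Per-timestep count fields (all non-negative integers).
COUNT_COLUMNS: tuple[str, ...] = (
    "executed_exams",
    "queued_exams_for_faults",
    "exams_no_additional_withdrawals",
    "exams_no_further_investigation",
    "exams_requiring_further_withdrawals",
    "effective_tests",
    "effective_exams_with_error",
    "exams_with_side_effects",
    "incoming_requests",
    "ethical_refusals_surgeon",
    "ethical_refusals_patient",
    "medical_specialists",
    "biologists",
    "planned_daily_exams",
)

#: Full per-timestep record schema: counts plus financial fields (currency).
TIMESTEP_COLUMNS: tuple[str, ...] = COUNT_COLUMNS + (
    "net_profit",
    "net_operating_margin",
    "net_revenues",
)

#: Indicator orientation: True = benefit (larger is better).
ORIENTATION: dict[str, bool] = {
    "technological_efficiency": True,
    "reliability": False,          # fault count: larger = less reliable
    "technological_safety": True,
    "procedural_complexity": False,
    "human_resources": True,
    "investments": True,           # investment/purchase-cost ratio: larger = lighter burden
    "usefulness": True,            # net profit over the window (a.k.a. profit)
    "ros": True,
    "clinical_efficiency": True,
    "effectiveness": True,
    "side_effects": False,
    "social": True,
    "legal": False,                # 1-10 scores with 1 best
    "ethical": False,              # refusals for ethical reasons
}

_SAFETY_VARS = (
    "visual_evaluation",
    "safety_standard_compliance",
    "manual_availability",
    "alarm_control_systems",
    "room_status",
)
_LEGAL_VARS = (
    "noise",
    "electromagnetic_pollution",
    "respect_value_of_life",
    "health_risk",
    "mandatory_standard_compliance",
    "lawsuits",
)


@dataclass(frozen=True)
class ScorePanel:
    """Expert scores and investment figures for one alternative.

    ``safety`` holds the five technological-safety variables and ``legal``
    the six legal-compliance variables, every score an integer 1-10 (for
    the legal variables 1 is the best value).  ``investment`` and
    ``purchase_cost`` are currency amounts feeding the investments ratio.
    """

    safety: Mapping[str, float] = field(default_factory=dict)
    legal: Mapping[str, float] = field(default_factory=dict)
    investment: float = 0.0
    purchase_cost: float = 1.0

    def __post_init__(self) -> None:
        for group, allowed in ((self.safety, _SAFETY_VARS), (self.legal, _LEGAL_VARS)):
            for name, score in group.items():
                if name not in allowed:
                    raise KeyError(f"unknown score variable {name!r}")
                if not 1 <= float(score) <= 10:
                    raise ValueError(f"score {name!r}={score} outside [1, 10]")
        if self.purchase_cost <= 0:
            raise ValueError("purchase cost must be positive")

    @property
    def safety_total(self) -> float:
        return float(sum(self.safety.values()))

    @property
    def legal_total(self) -> float:
        return float(sum(self.legal.values()))


@dataclass(frozen=True)
class IndicatorPanel:
    """One indicator value per sub-criterion for one alternative."""

    alternative: str
    values: dict[str, float]
    orientation: dict[str, bool] = field(default_factory=lambda: dict(ORIENTATION))

    def __getitem__(self, indicator: str) -> float:
        return self.values[indicator]


def _require(df: pd.DataFrame, columns: Sequence[str], indicator: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KeyError(f"indicator {indicator!r} needs missing column(s): {missing}")


def compute_indicator_panel(
    records: pd.DataFrame,
    scores: ScorePanel,
    alternative: str = "",
) -> IndicatorPanel:
    """Evaluate every sub-criterion indicator over an observation window.

    ``records`` holds one row per timestep for a single alternative, with
    the :data:`TIMESTEP_COLUMNS` schema.  Sum-type indicators aggregate
    over the whole window; ratio-type indicators are formed from window
    aggregates (procedural complexity = executed/planned daily exams,
    effectiveness = effective tests / incoming requests, ROS = net
    operating margin / net revenues, investments = investment / purchase
    cost).  Clinical efficiency is the surplus of exams needing no
    repetition over those requiring repeat withdrawals.

    Raises ``ValueError`` naming the indicator whenever a required
    denominator is non-positive.
    """
    if records.empty:
        raise ValueError("timestep record series is empty")
    counts = [c for c in COUNT_COLUMNS if c in records.columns]
    if (records[counts] < 0).any().any():
        raise ValueError("count columns must be non-negative")

    def total(col: str, indicator: str) -> float:
        _require(records, [col], indicator)
        return float(records[col].sum())

    def ratio(num: float, den: float, indicator: str) -> float:
        if den <= 0:
            raise ValueError(f"indicator {indicator!r}: denominator must be positive")
        return num / den

    values = {
        "technological_efficiency": total("executed_exams", "technological_efficiency"),
        "reliability": total("queued_exams_for_faults", "reliability"),
        "technological_safety": scores.safety_total,
        "procedural_complexity": ratio(
            total("executed_exams", "procedural_complexity"),
            total("planned_daily_exams", "procedural_complexity"),
            "procedural_complexity",
        ),
        "human_resources": total("medical_specialists", "human_resources")
        + total("biologists", "human_resources"),
        "investments": ratio(scores.investment, scores.purchase_cost, "investments"),
        "usefulness": total("net_profit", "usefulness"),
        "ros": ratio(
            total("net_operating_margin", "ros"),
            total("net_revenues", "ros"),
            "ros",
        ),
        "clinical_efficiency": (
            total("exams_no_additional_withdrawals", "clinical_efficiency")
            + total("exams_no_further_investigation", "clinical_efficiency")
            - total("exams_requiring_further_withdrawals", "clinical_efficiency")
        ),
        "effectiveness": ratio(
            total("effective_tests", "effectiveness"),
            total("incoming_requests", "effectiveness"),
            "effectiveness",
        ),
        "side_effects": total("exams_with_side_effects", "side_effects")
        + total("effective_exams_with_error", "side_effects"),
        "social": total("executed_exams", "social"),
        "legal": scores.legal_total,
        "ethical": total("ethical_refusals_surgeon", "ethical")
        + total("ethical_refusals_patient", "ethical"),
    }
    return IndicatorPanel(alternative=alternative, values=values)


def local_alternative_weights(
    values: Sequence[float] | np.ndarray,
    benefit: bool = True,
    mode: str = "reciprocal",
    eps: float = 1e-9,
) -> np.ndarray:
    """Normalize one indicator across alternatives into unit-sum weights.

    Benefit-type indicators share proportionally: ``w_i = v_i / sum(v)``.
    Cost-type indicators are transformed first so that smaller raw values
    earn larger weights; ``mode="reciprocal"`` (default) uses ``1 /
    max(v_i, eps)``, ``mode="max_minus"`` uses ``max(v) - v_i + min(v)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two alternatives")
    if np.any(v < 0):
        raise ValueError("indicator values must be non-negative")
    if not np.any(v > 0):
        raise ValueError("degenerate all-zero indicator vector")
    if not benefit:
        if mode == "reciprocal":
            v = 1.0 / np.maximum(v, eps)
        elif mode == "max_minus":
            v = v.max() - v + v.min() + eps
        else:
            raise ValueError(f"unknown cost-inversion mode {mode!r}")
    return v / v.sum()


def panel_local_weights(
    panels: Mapping[str, IndicatorPanel],
    mode: str = "reciprocal",
) -> pd.DataFrame:
    """Local alternative weights for every indicator, as leaves x alternatives.

    Rows are indicators (config order of :data:`ORIENTATION`), columns the
    alternatives; every row sums to 1.
    """
    alts = list(panels)
    if len(alts) < 2:
        raise ValueError("need panels for at least two alternatives")
    rows = {}
    for ind, benefit in ORIENTATION.items():
        vals = [panels[a].values[ind] for a in alts]
        rows[ind] = local_alternative_weights(vals, benefit=benefit, mode=mode)
    return pd.DataFrame.from_dict(rows, orient="index", columns=alts)
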
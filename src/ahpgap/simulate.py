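"""Synthetic survey and operational-data generator with known ground truth.

The original 80-expert survey and the clinics' operational logs are not
publicly deposited, so every pipeline stage is exercised against synthetic
studies generated here: pairwise judgments scattered multiplicatively
around a known priority vector, Likert answers drawn around per-item
satisfaction means, and per-timestep operational series from simple
Poisson/binomial processes.  All generators are pure functions of
(scenario, seed), so any run is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import RespondentJudgments, round_to_saaty
from .case_study import HIERARCHY_CONFIG, codebook as case_codebook
from .hierarchy import DecisionHierarchy, build_hierarchy
from .indicators import ScorePanel
from .likert import LikertCodebook

__all__ = [
    "AlternativeRates",
    "SurveyScenario",
    "generate_judgments",
    "generate_likert",
    "generate_timesteps",
    "case_study_scenario",
]

#: Node key used for the criteria-level comparison (children = criteria).
GOAL_NODE = "goal"


@dataclass(frozen=True)
class AlternativeRates:
    """Operational process rates for one alternative.

    Counts are generated per timestep (one timestep = one working day):
    exam requests arrive as Poisson(``arrival_rate``); executed, effective,
    erroneous, side-effect and repeat exams are binomial thinnings of the
    stream, which keeps the series internally consistent (e.g. effective
    tests never exceed incoming requests).  Faults and ethical refusals
    are independent Poisson streams.  Financial fields derive from the
    executed count: net revenues = executed x ``revenue_per_exam``, net
    operating margin = ``margin`` x revenues, net profit = executed x
    ``profit_per_exam``.
    """

    arrival_rate: float = 10.0
    execution_prob: float = 0.9
    effectiveness_prob: float = 0.85
    error_prob: float = 0.05
    side_effect_prob: float = 0.05
    repeat_prob: float = 0.1          # exams requiring further withdrawals
    investigation_prob: float = 0.1   # exams requiring further investigation
    fault_rate: float = 0.2
    refusal_rate_surgeon: float = 0.1
    refusal_rate_patient: float = 0.1
    medical_specialists: int = 2
    biologists: int = 2
    planned_daily_exams: int = 12
    revenue_per_exam: float = 100.0
    margin: float = 0.2
    profit_per_exam: float = 15.0

    def validate(self) -> None:
        probs = (self.execution_prob, self.effectiveness_prob, self.error_prob,
                 self.side_effect_prob, self.repeat_prob, self.investigation_prob)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        rates = (self.arrival_rate, self.fault_rate,
                 self.refusal_rate_surgeon, self.refusal_rate_patient)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")
        if self.refusal_rate_surgeon + self.refusal_rate_patient > self.arrival_rate:
            raise ValueError("total refusal rate cannot exceed the arrival rate")


@dataclass(frozen=True)
class SurveyScenario:
    """Complete description of one synthetic assessment study.

    ``truth`` maps each comparison node (``"goal"`` for the criteria
    level, a criterion name for its leaves) to the ground-truth unit-sum
    priority vector of its children; respondent k's judgment for children
    (i, j) is the Saaty rounding of ``(w_i / w_j) * exp(eps)`` with
    ``eps ~ Normal(0, noise^2)``, clamped to [1/9, 9].  ``noise`` is the
    log-scale standard deviation of that multiplicative perturbation
    (0 = perfectly consistent respondents).
    """

    hierarchy_config: Mapping = field(default_factory=lambda: HIERARCHY_CONFIG)
    truth: Mapping[str, Sequence[float]] = field(default_factory=dict)
    noise: float = 0.3
    n_respondents: int = 80
    likert_means: Mapping[int, float] = field(default_factory=dict)
    likert_dispersion: float = 0.8
    rates: Mapping[str, AlternativeRates] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be non-negative")
        if self.n_respondents < 1:
            raise ValueError("need at least one respondent")
        for node, vec in self.truth.items():
            v = np.asarray(vec, float)
            if np.any(v <= 0) or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"truth vector for {node!r} must be positive and unit-sum")
        for mean in self.likert_means.values():
            if not 1 <= mean <= 5:
                raise ValueError("Likert item means must lie in [1, 5]")
        for r in self.rates.values():
            r.validate()

    def hierarchy(self) -> DecisionHierarchy:
        return build_hierarchy(self.hierarchy_config)

    def comparison_nodes(self) -> dict[str, list[str]]:
        """node -> child labels for every pairwise-comparison battery."""
        h = self.hierarchy()
        nodes = {GOAL_NODE: h.criterion_names}
        for c in h.criteria:
            nodes[c.name] = list(c.subcriteria)
        return nodes


def _rng(scenario: SurveyScenario, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(scenario.seed if seed is None else seed)


def generate_judgments(
    scenario: SurveyScenario,
    seed: int | None = None,
) -> list[RespondentJudgments]:
    """Draw every respondent's pairwise judgments around the ground truth.

    Each judged ratio is ``round_to_saaty(clip((w_i/w_j) * exp(eps), 1/9,
    9))`` with independent log-normal perturbations per respondent and
    pair.  At ``noise=0`` every respondent reports the rounded truth
    ratios, so individual matrices are as consistent as Saaty rounding
    allows.
    """
    rng = _rng(scenario, seed)
    nodes = scenario.comparison_nodes()
    missing = [n for n in nodes if n not in scenario.truth]
    if missing:
        raise ValueError(f"scenario lacks truth vectors for nodes: {missing}")
    respondents = []
    for k in range(scenario.n_respondents):
        judgments = {}
        for node, labels in nodes.items():
            w = np.asarray(scenario.truth[node], float)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    ratio = (w[i] / w[j]) * np.exp(rng.normal(0.0, scenario.noise))
                    ratio = float(np.clip(ratio, 1 / 9, 9))
                    judgments[(node, labels[i], labels[j])] = float(round_to_saaty(ratio))
        respondents.append(RespondentJudgments(respondent_id=f"r{k+1:03d}",
                                               judgments=judgments))
    return respondents


def generate_likert(
    scenario: SurveyScenario,
    likert_codebook: LikertCodebook | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw raw categorical questionnaire answers around per-item means.

    Satisfaction scores are a discretized truncated normal: a draw from
    Normal(mean, dispersion) clipped to the scale range and rounded to the
    nearest level.  Scores are then emitted as the *category* a respondent
    with that satisfaction would tick — for reverse-coded items a satisfied
    respondent disagrees with the statement — so the raw table exercises
    the downstream coding step.  Returns long-form columns
    ``respondent_id``, ``item_id``, ``category``.
    """
    rng = _rng(scenario, seed)
    cb = likert_codebook or case_codebook()
    k = cb.n_points
    rows = []
    for r in range(scenario.n_respondents):
        rid = f"r{r+1:03d}"
        for item in cb.items:
            mean = float(scenario.likert_means.get(item.item_id, (1 + k) / 2))
            score = int(np.clip(np.rint(rng.normal(mean, scenario.likert_dispersion)), 1, k))
            # position 0 = strongest agreement; invert for direct items
            pos = score - 1 if item.reverse else k - score
            rows.append({"respondent_id": rid, "item_id": item.item_id,
                         "category": cb.categories[pos]})
    return pd.DataFrame(rows)


def generate_timesteps(
    scenario: SurveyScenario,
    n_timesteps: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the operational series feeding the indicator models.

    Returns one row per (timestep, alternative) with the full timestep
    record schema.  All count processes are Poisson arrivals with binomial
    thinning, so the internal consistency constraints hold by construction
    (executed <= incoming, effective <= executed, ...).
    """
    if n_timesteps < 1:
        raise ValueError("need at least one timestep")
    if not scenario.rates:
        raise ValueError("scenario defines no alternative rates")
    rng = _rng(scenario, seed)
    rows = []
    for alt, r in scenario.rates.items():
        r.validate()
        for t in range(n_timesteps):
            incoming = rng.poisson(r.arrival_rate)
            executed = rng.binomial(incoming, r.execution_prob) if incoming else 0
            effective = rng.binomial(executed, r.effectiveness_prob) if executed else 0
            with_error = rng.binomial(effective, r.error_prob) if effective else 0
            side = rng.binomial(executed, r.side_effect_prob) if executed else 0
            repeats = rng.binomial(executed, r.repeat_prob) if executed else 0
            investig = rng.binomial(executed, r.investigation_prob) if executed else 0
            refusals_s = rng.poisson(r.refusal_rate_surgeon)
            refusals_p = rng.poisson(r.refusal_rate_patient)
            revenues = executed * r.revenue_per_exam
            rows.append({
                "timestep": t,
                "alternative": alt,
                "incoming_requests": incoming,
                "executed_exams": executed,
                "effective_tests": effective,
                "effective_exams_with_error": with_error,
                "exams_with_side_effects": side,
                "exams_requiring_further_withdrawals": repeats,
                "exams_no_additional_withdrawals": executed - repeats,
                "exams_no_further_investigation": executed - investig,
                "queued_exams_for_faults": rng.poisson(r.fault_rate),
                "ethical_refusals_surgeon": refusals_s,
                "ethical_refusals_patient": refusals_p,
                "medical_specialists": r.medical_specialists,
                "biologists": r.biologists,
                "planned_daily_exams": r.planned_daily_exams,
                "net_revenues": revenues,
                "net_operating_margin": r.margin * revenues,
                "net_profit": executed * r.profit_per_exam,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Frozen study-condition fixture

#: Ground-truth priorities of the frozen scenario: the case study's group
#: eigenvector weights at each node, renormalized to exact unit sum.
_CASE_TRUTH_RAW: dict[str, tuple[float, ...]] = {
    GOAL_NODE: (0.0404, 0.0807, 0.4935, 0.2412, 0.1443),
    "technical": (3 / 7, 3 / 7, 1 / 7),
    "organizational": (5 / 6, 1 / 6),
    "economic": (0.1140, 0.4054, 0.4806),
    "clinical": (3 / 7, 3 / 7, 1 / 7),
    "social_ethical_legal": (0.1884, 0.0810, 0.7306),
}

#: Per-item satisfaction means of the frozen scenario, following the case
#: study's qualitative pattern: high satisfaction with technological safety,
#: staffing, side effects and social respect; low satisfaction with clinical
#: efficiency, effectiveness and treatment cost.
_CASE_LIKERT_MEANS: dict[int, float] = {
    1: 3.6, 2: 3.7, 3: 4.4, 4: 3.5, 5: 4.2, 6: 4.2, 7: 4.3,
    8: 2.6, 9: 2.8, 10: 2.7, 11: 4.2, 12: 3.8, 13: 3.9,
}


def case_study_scenario(seed: int = 0, noise: float = 0.3,
                        n_respondents: int = 80) -> SurveyScenario:
    """The frozen default test bed emulating the case-study conditions.

    Five criteria with fourteen sub-criterion leaves, three alternatives,
    80 respondents, judgment noise 0.3 on the log scale, and operational
    rates under which the LPG biosensor modestly outperforms the LOF
    biosensor, which outperforms cytological analysis.
    """
    truth = {
        node: tuple(np.asarray(v, float) / np.sum(v))
        for node, v in _CASE_TRUTH_RAW.items()
    }
    rates = {
        "cytological_analysis": AlternativeRates(
            arrival_rate=10.0, execution_prob=0.85, effectiveness_prob=0.75,
            error_prob=0.08, side_effect_prob=0.08, repeat_prob=0.15,
            investigation_prob=0.15, fault_rate=0.1, refusal_rate_surgeon=0.3,
            refusal_rate_patient=0.3, medical_specialists=3, biologists=2,
            planned_daily_exams=12, revenue_per_exam=80.0, margin=0.15,
            profit_per_exam=10.0,
        ),
        "biosensor_LOF": AlternativeRates(
            arrival_rate=12.0, execution_prob=0.92, effectiveness_prob=0.88,
            error_prob=0.04, side_effect_prob=0.03, repeat_prob=0.08,
            investigation_prob=0.08, fault_rate=0.3, refusal_rate_surgeon=0.1,
            refusal_rate_patient=0.1, medical_specialists=2, biologists=1,
            planned_daily_exams=12, revenue_per_exam=100.0, margin=0.22,
            profit_per_exam=16.0,
        ),
        "biosensor_LPG": AlternativeRates(
            arrival_rate=12.0, execution_prob=0.94, effectiveness_prob=0.92,
            error_prob=0.03, side_effect_prob=0.03, repeat_prob=0.06,
            investigation_prob=0.06, fault_rate=0.25, refusal_rate_surgeon=0.1,
            refusal_rate_patient=0.1, medical_specialists=2, biologists=1,
            planned_daily_exams=12, revenue_per_exam=100.0, margin=0.25,
            profit_per_exam=18.0,
        ),
    }
    return SurveyScenario(
        hierarchy_config=HIERARCHY_CONFIG,
        truth=truth,
        noise=noise,
        n_respondents=n_respondents,
        likert_means=dict(_CASE_LIKERT_MEANS),
        likert_dispersion=0.8,
        rates=rates,
        seed=seed,
    )


def case_score_panels() -> dict[str, ScorePanel]:
    """Fixed expert score panels for the three alternatives.

    Safety scores favour the engineered biosensors slightly; legal scores
    (1 = best) favour the established cytological workflow slightly.
    """
    def panel(safety: int, legal: int, investment: float, cost: float) -> ScorePanel:
        return ScorePanel(
            safety={v: safety for v in (
                "visual_evaluation", "safety_standard_compliance",
                "manual_availability", "alarm_control_systems", "room_status")},
            legal={v: legal for v in (
                "noise", "electromagnetic_pollution", "respect_value_of_life",
                "health_risk", "mandatory_standard_compliance", "lawsuits")},
            investment=investment, purchase_cost=cost,
        )

    return {
        "cytological_analysis": panel(7, 2, 30_000.0, 50_000.0),
        "biosensor_LOF": panel(8, 3, 60_000.0, 80_000.0),
        "biosensor_LPG": panel(8, 3, 65_000.0, 80_000.0),
    }


def scenario_with(scenario: SurveyScenario, **changes) -> SurveyScenario:
    """Frozen-dataclass convenience: a copy with fields replaced."""
    return replace(scenario, **changes)
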
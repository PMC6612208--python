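"""End-to-end assessment orchestration.

One call runs the whole chain: aggregate respondents' judgments into group
matrices, derive eigenvector priorities with consistency screening,
propagate local weights into global leaf weights, score the operational
indicators into alternative local weights, synthesize the final
alternative priorities, summarize the Likert questionnaire, and cross
importance with satisfaction in the gap table.  Stages whose inputs are
absent (timestep data, Likert answers) are simply omitted from the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import io as _io
from .aggregation import RespondentJudgments, group_matrices
from .ahp import (
    consistency,
    normalize_weights,
    principal_eigen,
    propagate_weights,
    synthesize_priorities,
)
from .gap import hierarchy_of_needs, importance_satisfaction
from .hierarchy import DecisionHierarchy
from .indicators import ScorePanel, compute_indicator_panel, panel_local_weights
from .likert import LikertCodebook, satisfaction_by_subcriterion, score_responses, summarize

logger = logging.getLogger("ahpgap")

REPORT_SCHEMA_VERSION = 1

#: Node key for the criteria-level battery (children = the criteria).
GOAL_NODE = "goal"


class StageError(RuntimeError):
    """An error raised by a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Options and inputs for a full assessment run."""

    hierarchy: DecisionHierarchy
    judgments: Sequence[RespondentJudgments]
    likert_answers: pd.DataFrame | None = None
    likert_codebook: LikertCodebook | None = None
    timesteps: pd.DataFrame | None = None
    score_panels: Mapping[str, ScorePanel] = field(default_factory=dict)
    cr_threshold: float = 0.1
    strict_consistency: bool = False
    rounding: bool = True
    cost_inversion: str = "reciprocal"
    gap_importance_cutoff: float | None = None
    gap_satisfaction_cutoff: float | None = None


def run_full_assessment(config: RunConfig) -> dict:
    """Run every applicable stage and return the structured report.

    The report is a JSON-serializable mapping with, per comparison node,
    the aggregated matrix, its consistency statistics and local weights;
    the global leaf weights and hierarchy of needs; and, when the inputs
    are present, the indicator-driven alternative priorities, the Likert
    satisfaction summary, and the importance-satisfaction gap table.
    """
    h = config.hierarchy
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "goal": h.goal,
        "alternatives": list(h.alternatives),
        "nodes": {},
    }

    # --- aggregation + eigen analysis per comparison node
    nodes = {GOAL_NODE: h.criterion_names}
    nodes.update({c.name: list(c.subcriteria) for c in h.criteria})
    try:
        matrices = group_matrices(config.judgments, nodes, rounding=config.rounding)
    except (ValueError, KeyError) as exc:
        raise StageError("aggregate", str(exc)) from exc

    local: dict[str, dict[str, float]] = {}
    for node, matrix in matrices.items():
        try:
            rep = consistency(matrix, threshold=config.cr_threshold,
                              strict=config.strict_consistency)
            _, raw = principal_eigen(matrix)
            wv = normalize_weights(raw, matrix.labels)
        except Exception as exc:
            raise StageError("priorities", f"node {node!r}: {exc}") from exc
        logger.info("node %s: %s", node, rep)
        local[node] = wv.as_dict()
        report["nodes"][node] = {
            "labels": list(matrix.labels),
            "matrix": matrix.values.tolist(),
            "lambda_max": rep.lambda_max,
            "ci": rep.ci,
            "ri": rep.ri,
            "cr": rep.cr,
            "consistency_acceptable": rep.acceptable,
            "local_weights": wv.as_dict(),
        }

    # --- weight propagation
    try:
        h.set_criterion_weights(local[GOAL_NODE])
        for c in h.criteria:
            h.set_subcriterion_weights(c.name, local[c.name])
        global_weights = propagate_weights(h)
    except (KeyError, ValueError) as exc:
        raise StageError("propagate", str(exc)) from exc
    report["criteria_weights"] = local[GOAL_NODE]
    report["global_weights"] = global_weights
    report["hierarchy_of_needs"] = [
        {"subcriterion": k, "weight": v} for k, v in hierarchy_of_needs(global_weights)
    ]

    # --- indicator models -> alternative priorities (optional)
    if config.timesteps is not None:
        try:
            panels = {}
            for alt in h.alternatives:
                records = config.timesteps[config.timesteps["alternative"] == alt]
                if records.empty:
                    raise ValueError(f"no timestep records for alternative {alt!r}")
                scores = config.score_panels.get(alt, ScorePanel())
                panels[alt] = compute_indicator_panel(records, scores, alternative=alt)
            local_alt = panel_local_weights(panels, mode=config.cost_inversion)
            contributions = {
                alt: [global_weights[leaf] * local_alt.loc[leaf, alt]
                      for leaf in h.leaves]
                for alt in h.alternatives
            }
            priorities = synthesize_priorities(contributions, labels=h.alternatives)
        except (KeyError, ValueError) as exc:
            raise StageError("indicators", str(exc)) from exc
        report["indicators"] = {a: p.values for a, p in panels.items()}
        report["alternative_local_weights"] = {
            leaf: {alt: float(local_alt.loc[leaf, alt]) for alt in h.alternatives}
            for leaf in h.leaves
        }
        report["alternative_priorities"] = {
            "totals": priorities.totals,
            "ranking": list(priorities.ranking),
            "unit_sum": priorities.unit_sum,
        }

    # --- Likert summary + gap analysis (optional)
    if config.likert_answers is not None:
        if config.likert_codebook is None:
            raise StageError("likert", "Likert answers given without a codebook")
        try:
            scored = score_responses(config.likert_answers, config.likert_codebook)
            summary = summarize(scored, n_points=config.likert_codebook.n_points)
            sat = satisfaction_by_subcriterion(summary, config.likert_codebook)
        except (KeyError, ValueError) as exc:
            raise StageError("likert", str(exc)) from exc
        report["likert_summary"] = {
            str(item): {k: float(v) for k, v in row.items()}
            for item, row in summary.iterrows()
        }
        report["satisfaction_by_subcriterion"] = sat

        shared = [leaf for leaf in h.leaves if leaf in sat]
        try:
            gap = importance_satisfaction(
                {leaf: global_weights[leaf] for leaf in shared},
                {leaf: sat[leaf] for leaf in shared},
                importance_cutoff=config.gap_importance_cutoff,
                satisfaction_cutoff=config.gap_satisfaction_cutoff,
            )
        except (KeyError, ValueError) as exc:
            raise StageError("gap", str(exc)) from exc
        report["gap"] = {
            "importance_cutoff": gap.attrs["importance_cutoff"],
            "satisfaction_cutoff": gap.attrs["satisfaction_cutoff"],
            "table": {
                leaf: {k: (bool(v) if k == "improve" else
                           v if isinstance(v, str) else float(v))
                       for k, v in row.items()}
                for leaf, row in gap.iterrows()
            },
        }
    return report


def write_report(report: dict, out_dir: str | Path) -> dict[str, Path]:
    """Emit report.json plus CSV views (weights.csv, gap.csv) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"report": out / "report.json"}
    _io.write_json(report, paths["report"])

    rows = []
    for node, info in report["nodes"].items():
        if node == GOAL_NODE:
            continue
        for leaf, w in info["local_weights"].items():
            rows.append({
                "criterion": node,
                "subcriterion": leaf,
                "criterion_weight": report["criteria_weights"][node],
                "local_weight": w,
                "overall_weight": report["global_weights"][leaf],
            })
    paths["weights"] = out / "weights.csv"
    pd.DataFrame(rows).to_csv(paths["weights"], index=False)

    if "gap" in report:
        paths["gap"] = out / "gap.csv"
        gap_df = pd.DataFrame.from_dict(report["gap"]["table"], orient="index")
        gap_df.index.name = "subcriterion"
        gap_df.to_csv(paths["gap"])
    return paths
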
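"""Group aggregation of individual pairwise judgments.

N respondents each judge the same sibling pairs; the group judgment for a
pair is the weighted geometric mean Π a_k^β_k of the individual ratios
(with β_k = 1/N when respondents are equally credible), optionally rounded
back to the nearest Saaty integer.  The geometric mean is the aggregation
rule that preserves the reciprocity of the group matrix: aggregating the
mirrored judgments 1/a_k yields exactly the reciprocal of the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .hierarchy import PairwiseMatrix

__all__ = ["RespondentJudgments", "wgmm", "round_to_saaty", "build_group_matrix"]

# (node, child_a, child_b) -> ratio of a over b
JudgmentKey = tuple[str, str, str]


@dataclass
class RespondentJudgments:
    """One respondent's pairwise judgments across the hierarchy.

    ``judgments`` maps ``(node, child_a, child_b)`` to the Saaty ratio of
    *child_a* over *child_b*.  ``weight`` is the respondent's credibility
    β_k; weights are renormalized to unit sum over whichever respondents
    contribute to a given pair.
    """

    respondent_id: str
    judgments: dict[JudgmentKey, float] = field(default_factory=dict)
    weight: float = 1.0

    def get(self, node: str, a: str, b: str) -> float | None:
        """Ratio of a over b at ``node``, following reciprocity if the
        pair was recorded in the opposite orientation."""
        if (node, a, b) in self.judgments:
            return float(self.judgments[(node, a, b)])
        if (node, b, a) in self.judgments:
            return 1.0 / float(self.judgments[(node, b, a)])
        return None


def wgmm(values: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Weighted geometric mean Π v_k^β_k of positive ratios.

    With ``weights=None`` all β_k = 1/N, i.e. the plain N-th-root geometric
    mean.  Computed in the log domain for numerical robustness.  Weights
    must be positive and sum to 1 (within 1e-9).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("wgmm needs at least one value")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("wgmm values must be positive and finite")
    if weights is None:
        return float(np.exp(np.mean(np.log(v))))
    b = np.asarray(weights, dtype=float)
    if b.shape != v.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(b <= 0):
        raise ValueError("weights must be positive")
    if abs(b.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {b.sum():.12g}, expected 1")
    return float(np.exp(np.sum(b * np.log(v))))


def round_to_saaty(g: float, ties: str = "up") -> Fraction:
    """Round an aggregated ratio to the nearest Saaty ratio.

    For g >= 1 the result is the nearest integer in 1..9.  For g < 1 the
    reciprocal is rounded instead and inverted, so that
    ``round_to_saaty(1/g) == 1 / round_to_saaty(g)`` always holds and
    reciprocity of a rounded group matrix is preserved.

    ``ties`` controls half-way values on the >= 1 side: "up" (2.5 -> 3,
    the default) or "down" (2.5 -> 2).
    """
    if ties not in ("up", "down"):
        raise ValueError(f"ties must be 'up' or 'down', got {ties!r}")
    g = float(g)
    if not np.isfinite(g) or g <= 0:
        raise ValueError(f"ratio must be positive and finite, got {g!r}")
    if g < 1.0:
        return 1 / round_to_saaty(1.0 / g, ties=ties)
    frac = g - np.floor(g)
    if frac == 0.5:
        k = int(np.floor(g)) + (1 if ties == "up" else 0)
    else:
        k = int(round(g))
    return Fraction(min(max(k, 1), 9))


def build_group_matrix(
    judgments: Sequence[RespondentJudgments],
    node: str,
    labels: Sequence[str],
    rounding: bool = True,
    ties: str = "up",
    missing: str = "drop",
) -> PairwiseMatrix:
    """Aggregate respondents into one group pairwise matrix for ``node``.

    Each upper-triangle entry is the weighted geometric mean of the
    respondents' ratios for that pair; with ``rounding`` (the default) it
    is then rounded to the nearest Saaty ratio on the >= 1 side of the pair
    and mirrored exactly, so the output always passes matrix validation.

    ``missing="drop"`` drops a respondent from any pair they did not judge
    and renormalizes the credibility weights over those present;
    ``missing="error"`` raises instead.
    """
    if not judgments:
        raise ValueError("need at least one respondent")
    if missing not in ("drop", "error"):
        raise ValueError(f"missing policy must be 'drop' or 'error', got {missing!r}")
    upper: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            vals, wts = [], []
            for r in judgments:
                v = r.get(node, a, b)
                if v is None:
                    if missing == "error":
                        raise ValueError(
                            f"respondent {r.respondent_id!r} did not judge "
                            f"({a!r}, {b!r}) at node {node!r}"
                        )
                    continue
                vals.append(v)
                wts.append(r.weight)
            if not vals:
                raise ValueError(f"no respondent judged pair ({a!r}, {b!r}) at {node!r}")
            beta = np.asarray(wts, float)
            g = wgmm(vals, beta / beta.sum())
            if rounding:
                # round on the >= 1 side only, then mirror: rounding both
                # orientations independently would break reciprocity
                entry = float(round_to_saaty(g, ties=ties))
            else:
                entry = g
            upper[(a, b)] = entry
    return PairwiseMatrix.from_judgments(list(labels), upper)


def group_matrices(
    judgments: Sequence[RespondentJudgments],
    nodes: Mapping[str, Sequence[str]],
    **kwargs,
) -> dict[str, PairwiseMatrix]:
    """Aggregate every node in ``nodes`` (node -> child labels)."""
    return {
        node: build_group_matrix(judgments, node, labels, **kwargs)
        for node, labels in nodes.items()
    }
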
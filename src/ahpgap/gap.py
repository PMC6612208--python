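"""Importance-satisfaction gap analysis.

The AHP side of the assessment yields a global importance weight for every
sub-criterion (the users' "hierarchy of needs"); the Likert side yields a
satisfaction index for the same sub-criteria.  Crossing the two identifies
where to act: a sub-criterion that users rate highly important but are
poorly satisfied with is the prime candidate for improvement, while high
satisfaction on low-importance items needs no intervention.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["hierarchy_of_needs", "importance_satisfaction"]


def hierarchy_of_needs(weights: Mapping[str, float]) -> list[tuple[str, float]]:
    """Sub-criteria sorted by descending global importance weight.

    Ties keep the input (config) order, so the ranking is deterministic.
    """
    items = list(weights.items())
    order = sorted(range(len(items)), key=lambda i: (-float(items[i][1]), i))
    return [(items[i][0], float(items[i][1])) for i in order]


def importance_satisfaction(
    importance: Mapping[str, float],
    satisfaction: Mapping[str, float],
    importance_cutoff: float | None = None,
    satisfaction_cutoff: float | None = None,
) -> pd.DataFrame:
    """Cross AHP importance with Likert satisfaction per sub-criterion.

    Both inputs must cover the same label set (a mismatch raises
    ``KeyError``).  Each sub-criterion is placed in an importance x
    satisfaction quadrant using the cutoffs (defaults: the median of each
    axis) and scored with the improvement priority

        priority = importance * (1 - satisfaction),

    which grows with importance and with dissatisfaction.  The returned
    frame has one row per sub-criterion, in input order, with columns
    ``importance``, ``satisfaction``, ``importance_rank``,
    ``satisfaction_rank``, ``quadrant``, ``priority``, ``priority_rank``
    and the boolean ``improve`` (high importance and low satisfaction).
    The cutoffs used are stored in ``frame.attrs``.
    """
    labels = list(importance)
    if set(labels) != set(satisfaction):
        only_i = sorted(set(labels) - set(satisfaction))
        only_s = sorted(set(satisfaction) - set(labels))
        raise KeyError(
            f"label mismatch between importance and satisfaction: "
            f"importance-only={only_i}, satisfaction-only={only_s}"
        )
    imp = np.array([float(importance[k]) for k in labels])
    sat = np.array([float(satisfaction[k]) for k in labels])
    if np.any((sat < 0) | (sat > 1)):
        raise ValueError("satisfaction indices must lie in [0, 1]")
    if importance_cutoff is None:
        importance_cutoff = float(np.median(imp))
    if satisfaction_cutoff is None:
        satisfaction_cutoff = float(np.median(sat))

    hi_imp = imp >= importance_cutoff
    hi_sat = sat >= satisfaction_cutoff
    quadrant = np.where(
        hi_imp & ~hi_sat, "high importance / low satisfaction",
        np.where(hi_imp & hi_sat, "high importance / high satisfaction",
                 np.where(~hi_imp & ~hi_sat, "low importance / low satisfaction",
                          "low importance / high satisfaction")),
    )
    priority = imp * (1.0 - sat)

    frame = pd.DataFrame(
        {
            "importance": imp,
            "satisfaction": sat,
            "importance_rank": _dense_rank(-imp),
            "satisfaction_rank": _dense_rank(-sat),
            "quadrant": quadrant,
            "priority": priority,
            "priority_rank": _dense_rank(-priority),
            "improve": hi_imp & ~hi_sat,
        },
        index=pd.Index(labels, name="subcriterion"),
    )
    frame.attrs["importance_cutoff"] = importance_cutoff
    frame.attrs["satisfaction_cutoff"] = satisfaction_cutoff
    return frame


def _dense_rank(values: np.ndarray) -> np.ndarray:
    """1-based ranks by ascending value, input order breaking ties."""
    order = sorted(range(len(values)), key=lambda i: (values[i], i))
    ranks = np.empty(len(values), dtype=int)
    for rank, i in enumerate(order, start=1):
        ranks[i] = rank
    return ranks


def plot_hierarchy_of_needs(weights: Mapping[str, float], ax=None):
    """Horizontal bar chart of the hierarchy of needs (descending)."""
    import matplotlib.pyplot as plt

    ranked = hierarchy_of_needs(weights)
    labels = [k for k, _ in ranked][::-1]
    vals = [v for _, v in ranked][::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * len(labels) + 1))
    ax.barh(labels, vals, color="steelblue")
    ax.set_xlabel("global importance weight")
    ax.set_title("Hierarchy of needs")
    return ax
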
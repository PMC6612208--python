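"""Likert questionnaire scoring and satisfaction summaries.

User satisfaction is surveyed with agreement statements answered on an
ordered categorical scale (default 5 points: strongly agree, agree,
uncertain, disagree, strongly disagree).  Positively phrased items score
strong agreement highest; reverse-coded items (statements where agreement
signals a problem, e.g. high procedural complexity) invert the direction
so that a high score always means high satisfaction.  Per-item summaries
report category frequency percentages, the mean score, and a satisfaction
index rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CATEGORIES",
    "LikertItem",
    "LikertCodebook",
    "score_responses",
    "summarize",
]

#: Agreement categories from strongest agreement to strongest disagreement.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "strongly agree",
    "agree",
    "uncertain",
    "disagree",
    "strongly disagree",
)


@dataclass(frozen=True)
class LikertItem:
    """One questionnaire statement.

    ``reverse`` items score strong agreement as 1 instead of the scale
    maximum.  ``subcriterion`` links the item to a hierarchy leaf for the
    downstream importance-satisfaction comparison.
    """

    item_id: int
    text: str
    subcriterion: str
    reverse: bool = False


@dataclass(frozen=True)
class LikertCodebook:
    """The item set and answer scale of one questionnaire.

    The scale width is configurable (4-7 points are common); categories
    are ordered from strongest agreement to strongest disagreement, so a
    direct item maps the first category to ``n_points`` and the last to 1,
    while a reverse item maps them the other way around.
    """

    items: tuple[LikertItem, ...]
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if not 2 <= len(self.categories) <= 9:
            raise ValueError("answer scale must have 2-9 categories")
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate item ids in codebook")

    @property
    def n_points(self) -> int:
        return len(self.categories)

    def item(self, item_id: int) -> LikertItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"unknown item id {item_id!r}")

    def score(self, item_id: int, category: str) -> int:
        """Numeric score of one answer under the item's coding direction."""
        it = self.item(item_id)
        key = category.strip().lower()
        cats = [c.lower() for c in self.categories]
        if key not in cats:
            raise KeyError(f"unknown answer category {category!r}")
        pos = cats.index(key)  # 0 = strongest agreement
        return pos + 1 if it.reverse else self.n_points - pos

    def subcriterion_map(self) -> dict[int, str]:
        return {it.item_id: it.subcriterion for it in self.items}


def score_responses(
    answers: pd.DataFrame,
    codebook: LikertCodebook,
) -> pd.DataFrame:
    """Convert raw categorical answers into a respondent x item score matrix.

    ``answers`` has columns ``respondent_id``, ``item_id``, ``category``.
    The output is a wide frame (rows = respondents, columns = item ids)
    holding scores 1..n_points, with NaN where a respondent skipped an
    item.  Unknown categories or item ids raise ``KeyError``.
    """
    required = {"respondent_id", "item_id", "category"}
    missing = required - set(answers.columns)
    if missing:
        raise KeyError(f"answers table missing column(s): {sorted(missing)}")
    scores = [
        codebook.score(int(row.item_id), str(row.category))
        for row in answers.itertuples(index=False)
    ]
    long = answers.assign(score=scores)
    wide = long.pivot_table(
        index="respondent_id", columns="item_id", values="score", aggfunc="first"
    )
    return wide.reindex(columns=[it.item_id for it in codebook.items])


def summarize(
    scored: pd.DataFrame,
    n_points: int | None = None,
) -> pd.DataFrame:
    """Per-item satisfaction summary of a scored response matrix.

    Returns one row per item with the frequency percentage of each score
    level (columns ``pct_1`` .. ``pct_k``, summing to 100), the number of
    respondents who answered (``n``), the mean score, and the
    satisfaction index ``(mean - 1) / (n_points - 1)`` in [0, 1].
    Missing answers are excluded item-wise.
    """
    if scored.empty:
        raise ValueError("no scored responses to summarize")
    if n_points is None:
        n_points = int(np.nanmax(scored.to_numpy(dtype=float)))
    levels = range(1, n_points + 1)
    rows = []
    for item in scored.columns:
        col = scored[item].dropna()
        if col.empty:
            raise ValueError(f"item {item!r} has no answers")
        counts = col.value_counts()
        n = len(col)
        row = {"item_id": item, "n": n}
        for lv in levels:
            row[f"pct_{lv}"] = 100.0 * counts.get(lv, 0) / n
        row["mean"] = float(col.mean())
        row["satisfaction_index"] = (row["mean"] - 1.0) / (n_points - 1)
        rows.append(row)
    return pd.DataFrame(rows).set_index("item_id")


def satisfaction_by_subcriterion(
    summary: pd.DataFrame,
    codebook: LikertCodebook,
) -> dict[str, float]:
    """Average the satisfaction index over items mapped to each leaf.

    Several items may probe the same sub-criterion (their indices are
    averaged); leaves not covered by any item are absent from the result.
    """
    mapping = codebook.subcriterion_map()
    acc: dict[str, list[float]] = {}
    for item_id, row in summary.iterrows():
        leaf = mapping.get(int(item_id))
        if leaf is None:
            raise KeyError(f"item {item_id!r} missing from codebook")
        acc.setdefault(leaf, []).append(float(row["satisfaction_index"]))
    return {leaf: float(np.mean(vals)) for leaf, vals in acc.items()}
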
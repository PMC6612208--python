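"""Built-in worked example: thyroglobulin biosensor assessment.

A published health-technology assessment compared three ways of assaying
thyroglobulin (Tg) in needle-aspiration samples from patients with
differentiated thyroid cancer: conventional cytological analysis (the
current practice), a lab-on-fibre optoelectronic biosensor (LOF, sensing
structures patterned on the fibre tip), and a long-period-grating
biosensor (LPG, gratings inscribed along the fibre core).  Eighty experts
judged five assessment dimensions — technical, organizational, economic,
clinical, and social/legal/ethical aspects — by pairwise comparison and
answered a 13-item satisfaction questionnaire.

This module ships the group-aggregated pairwise comparison matrices, the
questionnaire codebook, and the per-alternative leaf contribution lists of
that case study so the full pipeline can be exercised and its published
priorities reproduced without any external data.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .hierarchy import DecisionHierarchy, PairwiseMatrix, build_hierarchy
from .likert import LikertCodebook, LikertItem

__all__ = [
    "HIERARCHY_CONFIG",
    "hierarchy",
    "criteria_matrix",
    "subcriterion_matrices",
    "codebook",
    "ALTERNATIVE_CONTRIBUTIONS",
]

F = Fraction

#: Goal, criteria, sub-criteria and alternatives of the Tg assessment.
HIERARCHY_CONFIG: dict = {
    "goal": "Evaluate a new health technology to assay thyroglobulin",
    "criteria": [
        {
            "name": "technical",
            "subcriteria": ["reliability", "technological_efficiency", "technological_safety"],
        },
        {
            "name": "organizational",
            "subcriteria": ["procedural_complexity", "human_resources"],
        },
        {
            "name": "economic",
            "subcriteria": ["investments", "usefulness", "ros"],
        },
        {
            "name": "clinical",
            "subcriteria": ["clinical_efficiency", "effectiveness", "side_effects"],
        },
        {
            "name": "social_ethical_legal",
            "subcriteria": ["social", "legal", "ethical"],
        },
    ],
    "alternatives": ["cytological_analysis", "biosensor_LOF", "biosensor_LPG"],
}


def hierarchy() -> DecisionHierarchy:
    """A fresh (weights unset) copy of the case-study hierarchy."""
    return build_hierarchy(HIERARCHY_CONFIG)


def criteria_matrix() -> PairwiseMatrix:
    """Group pairwise comparison matrix of the five assessment dimensions.

    Each entry is the Saaty-rounded geometric mean of the 80 experts'
    judgments; e.g. economic aspects were judged very strongly more
    important than technical aspects (7).
    """
    labels = ("technical", "organizational", "economic", "clinical", "social_ethical_legal")
    rows = [
        [1, F(1, 3), F(1, 7), F(1, 5), F(1, 5)],
        [3, 1, F(1, 5), F(1, 3), F(1, 3)],
        [7, 5, 1, 3, 5],
        [5, 3, F(1, 3), 1, 3],
        [5, 3, F(1, 5), F(1, 3), 1],
    ]
    return PairwiseMatrix(labels, np.array(rows, dtype=float))


def subcriterion_matrices() -> dict[str, PairwiseMatrix]:
    """Group pairwise comparison matrices of each criterion's leaves."""
    mats = {
        "technical": (
            ("reliability", "technological_efficiency", "technological_safety"),
            [[1, 1, 3], [1, 1, 3], [F(1, 3), F(1, 3), 1]],
        ),
        "organizational": (
            ("procedural_complexity", "human_resources"),
            [[1, 5], [F(1, 5), 1]],
        ),
        "economic": (
            ("investments", "usefulness", "ros"),
            [[1, F(1, 3), F(1, 5)], [3, 1, 1], [5, 1, 1]],
        ),
        "clinical": (
            ("clinical_efficiency", "effectiveness", "side_effects"),
            [[1, 1, 3], [1, 1, 3], [F(1, 3), F(1, 3), 1]],
        ),
        "social_ethical_legal": (
            ("social", "legal", "ethical"),
            [[1, 3, F(1, 5)], [F(1, 3), 1, F(1, 7)], [5, 7, 1]],
        ),
    }
    return {
        node: PairwiseMatrix(labels, np.array(rows, dtype=float))
        for node, (labels, rows) in mats.items()
    }


def codebook() -> LikertCodebook:
    """The 13-item satisfaction questionnaire of the case study.

    Items 4, 8, 12 and 13 are reverse-coded: their printed score rows run
    1..5 from strong agreement to strong disagreement.
    """
    items = (
        LikertItem(1, "The reliability of the medical equipment is satisfactory",
                   "reliability"),
        LikertItem(2, "The technological efficiency is appropriate for the type of treatment",
                   "technological_efficiency"),
        LikertItem(3, "The technological safety is high to reduce any danger",
                   "technological_safety"),
        LikertItem(4, "The procedural complexity is quite easy and well organized",
                   "procedural_complexity", reverse=True),
        LikertItem(5, "The preparation of the medical staff is adequate",
                   "human_resources"),
        LikertItem(6, "The staff is adequately available",
                   "human_resources"),
        LikertItem(7, "The possible side effects of the treatment are not very dangerous "
                      "for the patients", "side_effects"),
        LikertItem(8, "The clinical efficacy of the treatment is evaluated as good",
                   "clinical_efficiency", reverse=True),
        LikertItem(9, "The cost of the treatment is appropriate for the quality offered",
                   "investments"),
        LikertItem(10, "The duration of the treatment is not long in relation to the type "
                       "of disease", "effectiveness"),
        LikertItem(11, "In the hospital, there is a good respect for social principles",
                   "social"),
        LikertItem(12, "The legal issues are respected", "legal", reverse=True),
        LikertItem(13, "The ethical principles are respected", "ethical", reverse=True),
    )
    return LikertCodebook(items=items)


#: Published per-leaf contributions (global leaf weight x local alternative
#: weight) of the three alternatives.  The leaf-by-leaf attribution was not
#: published, only the contribution lists; they are therefore kept as plain
#: sequences.  Note the cytological list's published total (0.334414) differs
#: from the sum of its published summands (0.3430); the pipeline sums summands.
ALTERNATIVE_CONTRIBUTIONS: dict[str, tuple[float, ...]] = {
    "cytological_analysis": (
        0.0114, 0.00042, 0.00960, 0.0105, 0.00512, 0.0228, 0.0270,
        0.0080, 0.0114, 0.0258, 0.01632, 0.0077, 0.00954, 0.1774,
    ),
    "biosensor_LOF": (
        0.00320, 0.00320, 0.00162, 0.0288, 0.00149, 0.0256, 0.0961,
        0.0961, 0.0450, 0.0046, 0.00544, 0.0018, 0.0477,
    ),
    "biosensor_LPG": (
        0.00270, 0.00270, 0.00376, 0.0288, 0.00149, 0.0256, 0.0811,
        0.1139, 0.0041, 0.00544, 0.0022, 0.0477, 0.0503, 0.0497,
    ),
}
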
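"""Decision hierarchy, Saaty judgment scale, and pairwise comparison matrices.

The analytic hierarchy process (AHP) decomposes a decision into a tree:
a goal, evaluation criteria, sub-criteria (the leaves carrying indicators),
and the alternatives being compared.  Judgments of relative importance
between siblings are expressed on Saaty's fundamental 1-9 ratio scale and
collected into positive reciprocal pairwise comparison matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Real
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SAATY_SCALE",
    "ANSWER_CATEGORIES",
    "saaty_value",
    "PairwiseMatrix",
    "validate_pairwise_matrix",
    "Criterion",
    "DecisionHierarchy",
    "build_hierarchy",
    "HierarchyConfigError",
]

#: Saaty's fundamental scale: judgment intensity -> descriptive label.
#: Even intensities are intermediate grades between the named odd ones.
SAATY_SCALE: dict[int, str] = {
    1: "Equal importance",
    2: "Weak",
    3: "Moderate importance",
    4: "Moderate plus",
    5: "Strong importance",
    6: "Strong plus",
    7: "Very strong or demonstrated importance",
    8: "Very, very strong",
    9: "Extreme importance",
}

#: Questionnaire answer categories for a pairwise comparison "A vs B".
#: The "more important" direction maps to the dominant intensity v, the
#: mirrored "less important" direction to the reciprocal 1/v.
ANSWER_CATEGORIES: dict[str, Fraction] = {
    "equally important": Fraction(1),
    "slightly more important": Fraction(3),
    "more important": Fraction(5),
    "much more important": Fraction(7),
    "extremely more important": Fraction(9),
    "slightly less important": Fraction(1, 3),
    "less important": Fraction(1, 5),
    "much less important": Fraction(1, 7),
    "extremely less important": Fraction(1, 9),
}

_LABEL_TO_INTENSITY = {label.lower(): v for v, label in SAATY_SCALE.items()}


def saaty_value(judgment: int | float | str | Fraction) -> Fraction:
    """Resolve a judgment expressed in any accepted form to an exact ratio.

    Accepts a scale intensity (1-9), a reciprocal ratio in [1/9, 1], a
    fraction string such as ``"1/7"``, a scale label ("Strong importance"),
    or a questionnaire answer category ("Much less important" -> 1/7).

    Returns the ratio as an exact :class:`fractions.Fraction`; reciprocals
    are exact rationals so that matrix reciprocity survives round-trips
    through text formats.
    """
    if isinstance(judgment, str):
        key = judgment.strip().lower()
        if key in _LABEL_TO_INTENSITY:
            return Fraction(_LABEL_TO_INTENSITY[key])
        if key in ANSWER_CATEGORIES:
            return ANSWER_CATEGORIES[key]
        try:
            value = Fraction(key)
        except (ValueError, ZeroDivisionError) as exc:
            raise KeyError(f"unknown Saaty judgment: {judgment!r}") from exc
        return _check_ratio(value, judgment)
    if isinstance(judgment, Real):
        return _check_ratio(Fraction(judgment).limit_denominator(10_000), judgment)
    raise KeyError(f"unknown Saaty judgment: {judgment!r}")


def _check_ratio(value: Fraction, original: object) -> Fraction:
    if not Fraction(1, 9) <= value <= 9:
        raise KeyError(f"judgment ratio {original!r} outside [1/9, 9]")
    return value


class HierarchyConfigError(ValueError):
    """Raised for malformed hierarchy definitions."""


@dataclass(frozen=True)
class PairwiseMatrix:
    """A positive reciprocal matrix of importance ratios among siblings.

    Parameters
    ----------
    labels
        Child node labels, in authoritative (config) order.
    values
        Square array with ``a[i, j]`` the importance of child *i* relative
        to child *j*; ``a[j, i] = 1 / a[i, j]`` and the diagonal is 1.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"pairwise matrix must be square, got shape {arr.shape}")
        if arr.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix dimension")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_judgments(
        cls,
        labels: Sequence[str],
        judgments: Mapping[tuple[str, str], float | Fraction],
    ) -> "PairwiseMatrix":
        """Build a matrix from upper-triangle judgments ``(a, b) -> ratio``.

        Reciprocity and the unit diagonal hold by construction: each pair is
        set once and mirrored exactly.
        """
        index = {lab: i for i, lab in enumerate(labels)}
        arr = np.eye(len(labels))
        seen: set[frozenset[str]] = set()
        for (a, b), ratio in judgments.items():
            if a not in index or b not in index:
                raise KeyError(f"judged pair ({a!r}, {b!r}) not among labels")
            if a == b:
                raise ValueError(f"self-comparison for {a!r}")
            pair = frozenset((a, b))
            if pair in seen:
                raise ValueError(f"duplicate judgment for pair ({a!r}, {b!r})")
            seen.add(pair)
            v = float(ratio)
            if v <= 0:
                raise ValueError(f"judgment for ({a!r}, {b!r}) must be positive")
            arr[index[a], index[b]] = v
            arr[index[b], index[a]] = 1.0 / v
        missing = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
            if frozenset((labels[i], labels[j])) not in seen
        ]
        if missing:
            raise ValueError(f"missing judgments for pairs: {missing}")
        return cls(tuple(labels), arr)

    def is_valid(self, tol: float = 1e-9) -> bool:
        return validate_pairwise_matrix(self, tol=tol)


def validate_pairwise_matrix(
    matrix: PairwiseMatrix | np.ndarray, tol: float = 1e-9
) -> bool:
    """Check the defining properties of a pairwise comparison matrix.

    True iff the matrix is square with n >= 2, strictly positive, finite,
    has unit diagonal, and satisfies reciprocity ``a_ij * a_ji = 1`` within
    ``tol``.
    """
    arr = matrix.values if isinstance(matrix, PairwiseMatrix) else np.asarray(matrix, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"pairwise matrix must be square, got shape {arr.shape}")
    n = arr.shape[0]
    if n < 2:
        return False
    if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
        return False
    if not np.allclose(np.diag(arr), 1.0, atol=tol):
        return False
    return bool(np.allclose(arr * arr.T, 1.0, atol=tol))


@dataclass
class Criterion:
    """A top-level criterion and its sub-criterion leaves."""

    name: str
    subcriteria: list[str]
    local_weight: float | None = None  # weight among sibling criteria
    sub_weights: dict[str, float] = field(default_factory=dict)  # local, unit-sum


@dataclass
class DecisionHierarchy:
    """Goal -> criteria -> sub-criteria -> alternatives tree.

    Local weights are unit-sum among siblings; the global weight of a leaf
    is the product of local weights down its path from the goal.  Weights
    are unset at construction and filled by the AHP engine.
    """

    goal: str
    criteria: list[Criterion]
    alternatives: list[str]

    def __post_init__(self) -> None:
        if not self.criteria:
            raise HierarchyConfigError("hierarchy needs at least one criterion")
        if len(self.alternatives) < 2:
            raise HierarchyConfigError("hierarchy needs at least two alternatives")
        names = [c.name for c in self.criteria]
        leaves = [s for c in self.criteria for s in c.subcriteria]
        for group, what in ((names, "criterion"), (leaves, "sub-criterion"),
                            (self.alternatives, "alternative")):
            dupes = {x for x in group if group.count(x) > 1}
            if dupes:
                raise HierarchyConfigError(f"duplicate {what} label(s): {sorted(dupes)}")
        for c in self.criteria:
            if not c.subcriteria:
                raise HierarchyConfigError(f"criterion {c.name!r} has no sub-criteria")

    @property
    def criterion_names(self) -> list[str]:
        return [c.name for c in self.criteria]

    @property
    def leaves(self) -> list[str]:
        """All sub-criterion labels in config order."""
        return [s for c in self.criteria for s in c.subcriteria]

    def parent_of(self, leaf: str) -> Criterion:
        for c in self.criteria:
            if leaf in c.subcriteria:
                return c
        raise KeyError(f"unknown sub-criterion {leaf!r}")

    def set_criterion_weights(self, weights: Mapping[str, float]) -> None:
        _check_unit_sum(weights, self.criterion_names, "criteria")
        for c in self.criteria:
            c.local_weight = float(weights[c.name])

    def set_subcriterion_weights(self, criterion: str, weights: Mapping[str, float]) -> None:
        crit = next((c for c in self.criteria if c.name == criterion), None)
        if crit is None:
            raise KeyError(f"unknown criterion {criterion!r}")
        _check_unit_sum(weights, crit.subcriteria, f"sub-criteria of {criterion!r}")
        crit.sub_weights = {s: float(weights[s]) for s in crit.subcriteria}


def _check_unit_sum(weights: Mapping[str, float], labels: Iterable[str], what: str) -> None:
    labels = list(labels)
    missing = [lab for lab in labels if lab not in weights]
    if missing:
        raise KeyError(f"missing weights for {what}: {missing}")
    total = sum(float(weights[lab]) for lab in labels)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"local weights for {what} sum to {total:.12g}, expected 1")


def build_hierarchy(config: Mapping) -> DecisionHierarchy:
    """Construct a validated :class:`DecisionHierarchy` from a config mapping.

    Expected keys: ``goal`` (str), ``criteria`` (list of ``{name,
    subcriteria}`` mappings, or mapping name -> list of sub-criteria),
    ``alternatives`` (list of str).  Node order is authoritative: every
    weight vector and matrix downstream is reported in this order.
    """
    try:
        goal = str(config["goal"])
        raw_criteria = config["criteria"]
        alternatives = [str(a) for a in config["alternatives"]]
    except KeyError as exc:
        raise HierarchyConfigError(f"hierarchy config missing key {exc}") from exc

    criteria: list[Criterion] = []
    if isinstance(raw_criteria, Mapping):
        items: Iterable = raw_criteria.items()
        for name, subs in items:
            criteria.append(Criterion(str(name), [str(s) for s in subs]))
    else:
        for entry in raw_criteria:
            criteria.append(
                Criterion(str(entry["name"]), [str(s) for s in entry["subcriteria"]])
            )
    return DecisionHierarchy(goal=goal, criteria=criteria, alternatives=alternatives)
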
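"""Eigenvector priorities, consistency screening, and weight synthesis.

Priorities are derived with Saaty's eigenvalue method: the principal right
eigenvector of a pairwise comparison matrix gives the relative weights of
the compared elements, and the gap between the principal eigenvalue λmax
and the dimension n measures judgment inconsistency through

    CI = (λmax - n) / (n - 1),    CR = CI / RI(n),

where RI(n) is Saaty's mean random consistency index.  Judgments with
CR <= 0.1 are conventionally considered acceptably consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .hierarchy import DecisionHierarchy, PairwiseMatrix, validate_pairwise_matrix

__all__ = [
    "RANDOM_INDEX",
    "ConsistencyReport",
    "WeightVector",
    "AlternativePriorities",
    "principal_eigen",
    "normalize_weights",
    "consistency",
    "propagate_weights",
    "synthesize_priorities",
    "InconsistentMatrixError",
]

#: Saaty's random consistency index by matrix dimension.  RI is the mean
#: CI of randomly filled reciprocal matrices; RI(5) = 1.12.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
}


class InconsistentMatrixError(ValueError):
    """Raised in strict mode when CR exceeds the acceptance threshold."""


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency statistics for one pairwise comparison matrix."""

    lambda_max: float
    n: int
    ci: float
    ri: float
    cr: float
    threshold: float
    acceptable: bool

    def __str__(self) -> str:
        verdict = "acceptable" if self.acceptable else "NOT acceptable"
        return (
            f"n={self.n}  lambda_max={self.lambda_max:.4f}  CI={self.ci:.4f}  "
            f"RI={self.ri:.2f}  CR={self.cr:.4f} ({self.cr:.2%}) -> {verdict}"
        )


@dataclass(frozen=True)
class WeightVector:
    """Priority weights for one sibling set.

    ``raw`` is the principal eigenvector scaled to unit Euclidean norm;
    ``normalized`` is the same direction rescaled to unit sum, the form
    used as local weights in the hierarchy.
    """

    labels: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return {lab: float(w) for lab, w in zip(self.labels, self.normalized)}


@dataclass(frozen=True)
class AlternativePriorities:
    """Final synthesized priorities of the alternatives."""

    labels: tuple[str, ...]
    contributions: dict[str, tuple[float, ...]]
    totals: dict[str, float]
    ranking: tuple[str, ...]  # descending by total, stable for ties
    unit_sum: bool  # whether the totals sum to 1 (within 1e-6)

    def normalized_totals(self) -> dict[str, float]:
        """Optional unit-sum view of the totals."""
        s = sum(self.totals.values())
        if s <= 0:
            raise ValueError("cannot normalize non-positive totals")
        return {k: v / s for k, v in self.totals.items()}


def principal_eigen(
    matrix: PairwiseMatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> tuple[float, np.ndarray]:
    """Principal eigenvalue and positive eigenvector of a reciprocal matrix.

    By Perron-Frobenius the largest eigenvalue of a positive matrix is real
    with a strictly positive eigenvector; it is returned scaled to unit
    Euclidean norm with all components positive (deterministic sign).
    Uses a dense eigensolver, falling back to power iteration if the dense
    result is degenerate.
    """
    arr = matrix.values if isinstance(matrix, PairwiseMatrix) else np.asarray(matrix, float)
    if not validate_pairwise_matrix(arr):
        raise ValueError("not a valid positive reciprocal matrix")
    eigvals, eigvecs = np.linalg.eig(arr)
    i = int(np.argmax(eigvals.real))
    lam = float(eigvals[i].real)
    vec = eigvecs[:, i].real
    if np.all(vec > 0) or np.all(vec < 0):
        vec = np.abs(vec)
    else:  # degenerate dense output: recover the Perron vector iteratively
        lam, vec = _power_iteration(arr, tol=tol, max_iter=max_iter)
    return lam, vec / np.linalg.norm(vec)


def _power_iteration(
    arr: np.ndarray, tol: float, max_iter: int
) -> tuple[float, np.ndarray]:
    v = np.full(arr.shape[0], 1.0 / np.sqrt(arr.shape[0]))
    lam = 0.0
    for _ in range(max_iter):
        w = arr @ v
        lam_new = float(np.linalg.norm(w))
        w /= lam_new
        if np.linalg.norm(w - v) < tol:
            return lam_new, w
        v, lam = w, lam_new
    raise RuntimeError(f"power iteration did not converge in {max_iter} steps")


def normalize_weights(
    raw: Sequence[float] | np.ndarray,
    labels: Sequence[str] | None = None,
) -> WeightVector:
    """Rescale a positive priority vector to unit sum.

    The output is invariant to any positive scaling of the input; the
    ``raw`` field stores the unit-Euclidean-norm representative.
    """
    v = np.asarray(raw, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValueError("weight vector must be 1-D and non-empty")
    if np.any(v < 0) or not np.any(v > 0):
        raise ValueError("weight components must be non-negative with a positive sum")
    if labels is None:
        labels = tuple(f"item_{i}" for i in range(v.size))
    return WeightVector(
        labels=tuple(labels),
        raw=v / np.linalg.norm(v),
        normalized=v / v.sum(),
    )


def consistency(
    matrix: PairwiseMatrix | np.ndarray,
    threshold: float = 0.1,
    strict: bool = False,
    random_index: Mapping[int, float] = RANDOM_INDEX,
) -> ConsistencyReport:
    """Consistency screening of a pairwise comparison matrix.

    CI = (λmax - n)/(n - 1) and CR = CI/RI(n).  For n <= 2 a reciprocal
    matrix is always consistent and CR is defined as 0.  A CR above the
    threshold warns by default (judgment sets slightly above 0.1 are often
    still used in practice); with ``strict=True`` it raises
    :class:`InconsistentMatrixError` instead.
    """
    arr = matrix.values if isinstance(matrix, PairwiseMatrix) else np.asarray(matrix, float)
    n = arr.shape[0]
    lam, _ = principal_eigen(arr)
    if n <= 2:
        ci, ri, cr = 0.0, 0.0, 0.0
    else:
        if n not in random_index:
            raise KeyError(f"no random index configured for n={n}")
        ci = (lam - n) / (n - 1)
        ri = random_index[n]
        cr = ci / ri
    acceptable = cr <= threshold
    report = ConsistencyReport(
        lambda_max=lam, n=n, ci=ci, ri=ri, cr=cr,
        threshold=threshold, acceptable=acceptable,
    )
    if not acceptable:
        if strict:
            raise InconsistentMatrixError(str(report))
        warnings.warn(f"consistency ratio above threshold: {report}", stacklevel=2)
    return report


def propagate_weights(hierarchy: DecisionHierarchy) -> dict[str, float]:
    """Global leaf weights: local sub-criterion weight x parent weight.

    Every sibling set must carry unit-sum local weights.  Because local
    weights are unit-sum at each level, the global leaf weights also sum
    to 1 (mass conservation down the tree).
    """
    for c in hierarchy.criteria:
        if c.local_weight is None:
            raise ValueError(f"criterion {c.name!r} has no local weight set")
        if set(c.sub_weights) != set(c.subcriteria):
            raise ValueError(f"criterion {c.name!r} has incomplete sub-criterion weights")
    return {
        leaf: c.local_weight * c.sub_weights[leaf]
        for c in hierarchy.criteria
        for leaf in c.subcriteria
    }


def synthesize_priorities(
    contributions: Mapping[str, Sequence[float]],
    labels: Sequence[str] | None = None,
) -> AlternativePriorities:
    """Aggregate per-leaf contributions into final alternative priorities.

    Each alternative's contribution list holds the products (global leaf
    weight x local alternative weight at that leaf); the alternative's
    total priority is their sum and the ranking sorts totals descending
    with stable tie order.  Totals are reported as-is — they sum to 1 only
    when every leaf contributed a complete unit-sum local weight vector —
    and ``unit_sum`` records whether they do; a normalized view is
    available via :meth:`AlternativePriorities.normalized_totals`.
    """
    if labels is None:
        labels = tuple(contributions.keys())
    labels = tuple(labels)
    contribs: dict[str, tuple[float, ...]] = {}
    totals: dict[str, float] = {}
    for alt in labels:
        vals = tuple(float(v) for v in contributions[alt])
        if any(v < 0 for v in vals):
            raise ValueError(f"negative contribution for alternative {alt!r}")
        contribs[alt] = vals
        totals[alt] = float(sum(vals))
    order = sorted(range(len(labels)), key=lambda i: (-totals[labels[i]], i))
    return AlternativePriorities(
        labels=labels,
        contributions=contribs,
        totals=totals,
        ranking=tuple(labels[i] for i in order),
        unit_sum=abs(sum(totals.values()) - 1.0) <= 1e-6,
    )
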
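import numpy as np
import pytest

from ahpgap.case_study import (
    ALTERNATIVE_CONTRIBUTIONS,
    codebook,
    criteria_matrix,
    hierarchy,
    subcriterion_matrices,
)
from ahpgap.simulate import case_study_scenario


@pytest.fixture(scope="session")
def crit_matrix():
    """The 5x5 group comparison matrix of the assessment dimensions."""
    return criteria_matrix()


@pytest.fixture(scope="session")
def sub_matrices():
    return subcriterion_matrices()


@pytest.fixture
def case_hierarchy():
    return hierarchy()


@pytest.fixture(scope="session")
def case_codebook():
    return codebook()


@pytest.fixture(scope="session")
def contributions():
    return ALTERNATIVE_CONTRIBUTIONS


@pytest.fixture
def scenario():
    """Frozen study-condition scenario (seed 0)."""
    return case_study_scenario(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_reciprocal(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random positive reciprocal matrix with Saaty-range entries."""
    arr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = float(rng.integers(1, 10)) ** float(rng.choice([-1.0, 1.0]))
            arr[i, j] = v
            arr[j, i] = 1.0 / v
    return arr


def consistent_matrix(weights: np.ndarray) -> np.ndarray:
    """The fully consistent matrix a_ij = w_i / w_j."""
    w = np.asarray(weights, float)
    return np.outer(w, 1.0 / w)
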
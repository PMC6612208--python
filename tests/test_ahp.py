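"""Eigenvector priorities, consistency statistics, and weight synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahpgap.ahp import (
    InconsistentMatrixError,
    _power_iteration,
    consistency,
    normalize_weights,
    principal_eigen,
    propagate_weights,
    synthesize_priorities,
)
from ahpgap.hierarchy import build_hierarchy

from .conftest import consistent_matrix, random_reciprocal


def _det_scan_largest_root(arr: np.ndarray, lo: float, hi: float) -> float:
    """Brute-force oracle: largest root of det(M - x I) by grid scan + bisection."""
    f = lambda x: np.linalg.det(arr - x * np.eye(arr.shape[0]))
    xs = np.linspace(lo, hi, 20_000)
    vals = [f(x) for x in xs]
    root = None
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            root = xs[i]
        elif vals[i] * vals[i + 1] < 0:
            a, b = xs[i], xs[i + 1]
            for _ in range(200):
                m = 0.5 * (a + b)
                if f(a) * f(m) <= 0:
                    b = m
                else:
                    a = m
            root = 0.5 * (a + b)
    assert root is not None, "no real root found in scan range"
    return root


class TestPrincipalEigen:
    def test_case_study_matrix(self, crit_matrix):
        lam, raw = principal_eigen(crit_matrix)
        assert lam == pytest.approx(5.3185, abs=1e-3)
        expected = [0.0703, 0.1403, 0.8582, 0.4194, 0.2509]
        assert np.allclose(raw, expected, atol=1e-3)
        assert np.linalg.norm(raw) == pytest.approx(1.0)

    def test_consistent_matrix_exact(self):
        arr = np.array([[1, 2, 4], [0.5, 1, 2], [0.25, 0.5, 1]])
        lam, raw = principal_eigen(arr)
        assert lam == pytest.approx(3.0, abs=1e-12)
        assert np.allclose(raw / raw[2], [4, 2, 1], atol=1e-10)

    def test_matches_determinant_scan_oracle(self, rng):
        for _ in range(5):
            arr = random_reciprocal(rng, 4)
            lam, _ = principal_eigen(arr)
            oracle = _det_scan_largest_root(arr, lo=3.5, hi=40.0)
            assert lam == pytest.approx(oracle, abs=1e-6)

    def test_matches_power_iteration(self, rng):
        for n in range(3, 8):
            arr = random_reciprocal(rng, n)
            lam_d, v_d = principal_eigen(arr)
            lam_p, v_p = _power_iteration(arr, tol=1e-14, max_iter=100_000)
            assert lam_d == pytest.approx(lam_p, abs=1e-9)
            assert np.allclose(v_d, v_p, atol=1e-9)

    def test_lambda_max_at_least_n(self, rng):
        for n in range(3, 8):
            lam, _ = principal_eigen(random_reciprocal(rng, n))
            assert lam >= n - 1e-9

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            principal_eigen(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestNormalizeWeights:
    def test_case_study_normalization(self):
        raw = [0.0703, 0.1403, 0.8582, 0.4194, 0.2509]
        wv = normalize_weights(raw)
        assert np.allclose(wv.normalized, [0.0404, 0.0807, 0.4935, 0.2412, 0.1443],
                           atol=1e-3)
        assert wv.normalized.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform(self):
        assert np.allclose(normalize_weights([1, 1, 1, 1]).normalized, 0.25)

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(0.01, 100, allow_nan=False), min_size=2, max_size=8),
        st.floats(0.001, 1000, allow_nan=False),
    )
    def test_scale_invariance(self, v, c):
        a = normalize_weights(v).normalized
        b = normalize_weights([c * x for x in v]).normalized
        assert np.allclose(a, b, rtol=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights([0.0, 0.0])


class TestConsistency:
    def test_case_study_matrix(self, crit_matrix):
        rep = consistency(crit_matrix)
        assert rep.ci == pytest.approx(0.0796, abs=5e-4)
        assert rep.ri == 1.12
        assert rep.cr == pytest.approx(0.0711, abs=5e-4)
        assert rep.acceptable

    def test_fully_consistent_is_zero(self, rng):
        for n in range(3, 8):
            arr = consistent_matrix(rng.uniform(0.2, 5.0, size=n))
            rep = consistency(arr)
            assert rep.ci == pytest.approx(0.0, abs=1e-9)
            assert rep.cr == pytest.approx(0.0, abs=1e-9)

    def test_perturbed_matrix_matches_hand_formula(self):
        arr = np.array([[1, 2, 4], [0.5, 1, 3], [0.25, 1 / 3, 1]])
        lam, _ = principal_eigen(arr)
        rep = consistency(arr)
        assert rep.cr == pytest.approx((lam - 3) / 2 / 0.58, abs=1e-12)

    def test_2x2_defined_as_zero(self):
        rep = consistency(np.array([[1, 7], [1 / 7, 1]]))
        assert rep.cr == 0.0 and rep.acceptable

    def test_above_threshold_warns_by_default(self):
        bad = np.array([[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]])
        with pytest.warns(UserWarning, match="consistency ratio"):
            rep = consistency(bad)
        assert not rep.acceptable

    def test_strict_mode_raises(self):
        bad = np.array([[1, 9, 1 / 9], [1 / 9, 1, 9], [9, 1 / 9, 1]])
        with pytest.raises(InconsistentMatrixError):
            consistency(bad, strict=True)

    def test_unknown_dimension_rejected(self):
        with pytest.raises(KeyError):
            consistency(random_reciprocal(np.random.default_rng(0), 10))


class TestPropagateWeights:
    def test_case_study_overall_weights(self, case_hierarchy):
        h = case_hierarchy
        h.set_criterion_weights({
            "technical": 0.0404, "organizational": 0.08065, "economic": 0.4933,
            "clinical": 0.2413, "social_ethical_legal": 0.14435,
        })
        h.set_subcriterion_weights("clinical", {
            "clinical_efficiency": 0.4286, "effectiveness": 0.4286,
            "side_effects": 0.1428,
        })
        for c, w in (("technical", [0.4286, 0.4286, 0.1428]),
                     ("organizational", [5 / 6, 1 / 6]),
                     ("economic", [0.1140, 0.4054, 0.4806]),
                     ("social_ethical_legal", [0.1884, 0.0810, 0.7306])):
            crit = next(x for x in h.criteria if x.name == c)
            total = sum(w)
            h.set_subcriterion_weights(c, {s: v / total
                                           for s, v in zip(crit.subcriteria, w)})
        glob = propagate_weights(h)
        assert glob["clinical_efficiency"] == pytest.approx(0.1034, abs=2e-4)
        assert glob["ros"] == pytest.approx(0.237, abs=1e-3)
        assert sum(glob.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_leaf_pass_through(self):
        h = build_hierarchy({
            "goal": "g",
            "criteria": [{"name": "c1", "subcriteria": ["x"]},
                         {"name": "c2", "subcriteria": ["y"]}],
            "alternatives": ["a", "b"],
        })
        h.set_criterion_weights({"c1": 0.3, "c2": 0.7})
        h.set_subcriterion_weights("c1", {"x": 1.0})
        h.set_subcriterion_weights("c2", {"y": 1.0})
        assert propagate_weights(h)["x"] == pytest.approx(0.3)

    def test_mass_conservation_random(self, rng):
        h = build_hierarchy({
            "goal": "g",
            "criteria": [{"name": f"c{i}", "subcriteria": [f"s{i}{j}" for j in range(3)]}
                         for i in range(4)],
            "alternatives": ["a", "b"],
        })
        cw = rng.dirichlet(np.ones(4))
        h.set_criterion_weights({f"c{i}": cw[i] for i in range(4)})
        for i in range(4):
            sw = rng.dirichlet(np.ones(3))
            h.set_subcriterion_weights(f"c{i}", {f"s{i}{j}": sw[j] for j in range(3)})
        assert sum(propagate_weights(h).values()) == pytest.approx(1.0, abs=1e-9)

    def test_unset_weight_errors(self, case_hierarchy):
        with pytest.raises(ValueError, match="no local weight"):
            propagate_weights(case_hierarchy)

    def test_non_unit_sum_rejected(self, case_hierarchy):
        with pytest.raises(ValueError, match="sum to"):
            case_hierarchy.set_criterion_weights(
                {c: 0.3 for c in case_hierarchy.criterion_names})


class TestSynthesizePriorities:
    def test_case_study_totals_and_ranking(self, contributions):
        res = synthesize_priorities(contributions)
        assert res.totals["biosensor_LOF"] == pytest.approx(0.36065, abs=1e-12)
        assert res.totals["biosensor_LPG"] == pytest.approx(0.419, abs=5e-4)
        assert res.ranking == ("biosensor_LPG", "biosensor_LOF", "cytological_analysis")
        assert not res.unit_sum

    def test_tied_totals_keep_input_order(self):
        res = synthesize_priorities({"x": [0.2, 0.3], "y": [0.25, 0.25]})
        assert res.ranking == ("x", "y")

    def test_permutation_invariance_of_totals(self, rng, contributions):
        base = synthesize_priorities(contributions).totals
        shuffled = {a: list(rng.permutation(list(v)))
                    for a, v in contributions.items()}
        got = synthesize_priorities(shuffled).totals
        for alt in base:
            assert got[alt] == pytest.approx(base[alt], rel=1e-12)

    def test_negative_contribution_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            synthesize_priorities({"a": [0.1, -0.2], "b": [0.3]})

    def test_normalized_view_sums_to_one(self, contributions):
        norm = synthesize_priorities(contributions).normalized_totals()
        assert sum(norm.values()) == pytest.approx(1.0)
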
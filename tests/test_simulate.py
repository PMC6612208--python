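"""Synthetic study generators: determinism, consistency, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from ahpgap.aggregation import build_group_matrix, round_to_saaty
from ahpgap.ahp import consistency, principal_eigen
from ahpgap.hierarchy import PairwiseMatrix
from ahpgap.indicators import compute_indicator_panel
from ahpgap.simulate import (
    GOAL_NODE,
    AlternativeRates,
    SurveyScenario,
    generate_judgments,
    generate_likert,
    generate_timesteps,
    case_study_scenario,
    scenario_with,
)
from ahpgap.simulate import case_score_panels

SIMPLE_CONFIG = {
    "goal": "g",
    "criteria": [{"name": "c1", "subcriteria": ["x", "y", "z"]}],
    "alternatives": ["a", "b"],
}


def simple_scenario(**kw):
    defaults = dict(
        hierarchy_config=SIMPLE_CONFIG,
        truth={GOAL_NODE: (1.0,), "c1": (4 / 7, 2 / 7, 1 / 7)},
        noise=0.0,
        n_respondents=5,
        seed=0,
    )
    defaults.update(kw)
    return SurveyScenario(**defaults)


class TestGenerateJudgments:
    def test_zero_noise_yields_fully_consistent_matrices(self):
        """Truth [4/7, 2/7, 1/7] has exact Saaty ratios 2, 4, 2, so every
        noiseless respondent is perfectly consistent (CR = 0)."""
        judgments = generate_judgments(simple_scenario())
        for r in judgments:
            m = PairwiseMatrix.from_judgments(
                ["x", "y", "z"],
                {("x", "y"): r.judgments[("c1", "x", "y")],
                 ("x", "z"): r.judgments[("c1", "x", "z")],
                 ("y", "z"): r.judgments[("c1", "y", "z")]},
            )
            assert consistency(m).cr == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical(self, scenario):
        a = generate_judgments(scenario, seed=1)
        b = generate_judgments(scenario, seed=1)
        assert [r.judgments for r in a] == [r.judgments for r in b]

    def test_different_seeds_differ(self, scenario):
        a = generate_judgments(scenario, seed=1)
        b = generate_judgments(scenario, seed=2)
        assert [r.judgments for r in a] != [r.judgments for r in b]

    def test_all_ratios_on_saaty_scale(self, scenario):
        for r in generate_judgments(scenario, seed=3)[:10]:
            for v in r.judgments.values():
                assert v == float(round_to_saaty(v))

    def test_missing_truth_vector_rejected(self, scenario):
        broken = scenario_with(scenario, truth={GOAL_NODE: scenario.truth[GOAL_NODE]})
        with pytest.raises(ValueError, match="truth vectors"):
            generate_judgments(broken)

    def test_noisy_group_recovery_within_pilot_tolerance(self):
        """At noise 0.3 and N = 80 the aggregated eigenvector stays close to
        truth; tolerances frozen from a 100-replicate pilot (L1 mean 0.053,
        max 0.079 with Saaty-rounded aggregation)."""
        truth = np.asarray(case_study_scenario().truth[GOAL_NODE])
        for seed in (0, 1, 2):
            sc = case_study_scenario(seed=seed, noise=0.3)
            m = build_group_matrix(generate_judgments(sc), GOAL_NODE,
                                   sc.hierarchy().criterion_names)
            _, raw = principal_eigen(m)
            assert np.abs(raw / raw.sum() - truth).sum() < 0.08


class TestGenerateLikert:
    def test_point_mass_at_scale_top(self, scenario, case_codebook):
        sc = scenario_with(scenario, likert_means={i: 5.0 for i in range(1, 14)},
                           likert_dispersion=0.0)
        answers = generate_likert(sc)
        direct = {it.item_id for it in case_codebook.items if not it.reverse}
        for row in answers.itertuples(index=False):
            expected = ("strongly agree" if row.item_id in direct
                        else "strongly disagree")
            assert row.category == expected
            assert case_codebook.score(row.item_id, row.category) == 5

    def test_sample_mean_near_target(self, scenario, case_codebook):
        sc = scenario_with(scenario, likert_means={i: 3.0 for i in range(1, 14)})
        answers = generate_likert(sc, seed=11)
        from ahpgap.likert import score_responses
        wide = score_responses(answers, case_codebook)
        assert wide.to_numpy().mean() == pytest.approx(3.0, abs=0.2)

    def test_same_seed_identical(self, scenario):
        pd.testing.assert_frame_equal(generate_likert(scenario, seed=5),
                                      generate_likert(scenario, seed=5))

    def test_out_of_scale_mean_rejected(self, scenario):
        with pytest.raises(ValueError, match="\\[1, 5\\]"):
            scenario_with(scenario, likert_means={1: 6.0})


class TestGenerateTimesteps:
    def test_null_process(self, scenario):
        zero = AlternativeRates(arrival_rate=0, fault_rate=0,
                                refusal_rate_surgeon=0, refusal_rate_patient=0,
                                medical_specialists=0, biologists=0,
                                planned_daily_exams=0)
        sc = scenario_with(scenario, rates={"a": zero, "b": zero})
        df = generate_timesteps(sc, 20)
        count_cols = [c for c in df.columns if c not in ("timestep", "alternative")]
        assert (df[count_cols] == 0).all().all()

    def test_poisson_concentration(self, scenario):
        rates = AlternativeRates(arrival_rate=10.0, execution_prob=1.0)
        sc = scenario_with(scenario, rates={"a": rates, "b": rates})
        df = generate_timesteps(sc, 100, seed=2)
        total = df[df["alternative"] == "a"]["executed_exams"].sum()
        assert abs(total - 1000) < 3 * np.sqrt(1000)

    def test_internal_consistency(self, scenario):
        df = generate_timesteps(scenario, 50, seed=3)
        assert (df["executed_exams"] <= df["incoming_requests"]).all()
        assert (df["effective_tests"] <= df["executed_exams"]).all()
        assert (df["effective_exams_with_error"] <= df["effective_tests"]).all()
        assert (df["exams_no_additional_withdrawals"]
                + df["exams_requiring_further_withdrawals"]
                == df["executed_exams"]).all()

    def test_effectiveness_separates_alternatives(self, scenario):
        """The LPG biosensor's configured effectiveness exceeds cytology's in
        at least 95 of 100 seeded replicates (pilot-established margin)."""
        panels = case_score_panels()
        wins = 0
        for seed in range(100):
            df = generate_timesteps(scenario, 10, seed=seed)
            eff = {}
            for alt in ("biosensor_LPG", "cytological_analysis"):
                sub = df[df["alternative"] == alt]
                eff[alt] = compute_indicator_panel(
                    sub, panels[alt], alternative=alt)["effectiveness"]
            wins += eff["biosensor_LPG"] > eff["cytological_analysis"]
        assert wins >= 95

    def test_impossible_rates_rejected(self):
        with pytest.raises(ValueError, match="refusal"):
            AlternativeRates(arrival_rate=0.1, refusal_rate_surgeon=1.0).validate()

    def test_same_seed_identical(self, scenario):
        pd.testing.assert_frame_equal(generate_timesteps(scenario, 10, seed=9),
                                      generate_timesteps(scenario, 10, seed=9))


class TestEndToEndRecovery:
    def test_zero_noise_reconstruction_is_rounded_truth(self):
        """A noiseless survey reproduces, at every node, exactly the matrix of
        Saaty-rounded (and [1/9, 9]-clamped) truth ratios, and its eigenvector
        recovers the truth up to the rounding floor (< 0.04 per component for
        the case-study truth)."""
        sc = case_study_scenario(seed=0, noise=0.0)
        judgments = generate_judgments(sc)
        for node, labels in sc.comparison_nodes().items():
            if len(labels) < 2:
                continue
            w = np.asarray(sc.truth[node])
            m = build_group_matrix(judgments, node, labels)
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    expected = float(round_to_saaty(np.clip(w[i] / w[j], 1 / 9, 9)))
                    assert m.values[i, j] == expected, (node, i, j)
            _, raw = principal_eigen(m)
            assert np.abs(raw / raw.sum() - w).max() < 0.04, node

    def test_recovery_error_decreases_with_panel_size(self):
        """Mean L1 distance between the aggregated (raw WGMM) eigenvector and
        truth shrinks as the respondent panel grows."""
        truth = np.asarray(case_study_scenario().truth[GOAL_NODE])
        means = []
        for n in (5, 80):
            errs = []
            for seed in range(30):
                sc = case_study_scenario(seed=seed, noise=0.3, n_respondents=n)
                m = build_group_matrix(generate_judgments(sc), GOAL_NODE,
                                       sc.hierarchy().criterion_names,
                                       rounding=False)
                _, raw = principal_eigen(m)
                errs.append(np.abs(raw / raw.sum() - truth).sum())
            means.append(np.mean(errs))
        assert means[1] < means[0]
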
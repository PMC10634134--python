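"""Cohort reconstruction, worked examples, and the trial simulator."""

import numpy as np
import pytest
from scipy.special import expit, logit

from histborrow.cohorts import (ARM_CONTROL, ARM_PMX, CovariateModel,
                                TrialDataset, counts_matching_percent,
                                default_shared_apache, derive_historical_counts,
                                generate_trial_dataset, make_worked_example,
                                reconstruct_treatable_cohort,
                                solve_marginal_intercept, worked_example_suite)
from histborrow.oc import Scenario


class TestHistoricalCohort:
    def test_death_counts_are_unique_and_match_printed_percentages(self):
        # brute-force oracle: enumerate every d and keep those that round back
        assert [d for d in range(91) if round(100 * d / 90, 1) == 36.7] == [33]
        assert [d for d in range(90) if round(100 * d / 89, 1) == 47.2] == [42]
        assert derive_historical_counts() == (33, 42)
        assert counts_matching_percent(36.7, 90) == [33]

    def test_reconstructed_cohort_reproduces_the_published_margins(self, cohort):
        s = cohort.summarize()
        assert (s.n_pmx, s.n_ctrl) == (90, 89)
        assert s.n_total == 179
        assert (s.deaths_pmx, s.deaths_ctrl) == (33, 42)
        assert round(100 * s.risk_pmx, 1) == 36.7
        assert round(100 * s.risk_ctrl, 1) == 47.2
        assert cohort.source == "historical"

    def test_cohort_is_deterministic_under_seed_and_respects_score_bounds(self):
        a = reconstruct_treatable_cohort(seed=11)
        b = reconstruct_treatable_cohort(seed=11)
        c = reconstruct_treatable_cohort(seed=12)
        assert a.df.equals(b.df)
        assert not a.df.equals(c.df)
        assert a.df["apache"].between(0, 71).all()


class TestWorkedExamples:
    def test_contingency_margins(self, suite):
        for d, ds in suite.items():
            s = ds.summarize()
            assert (s.deaths_pmx, s.n_pmx, s.deaths_ctrl, s.n_ctrl) == (d, 100, 22, 50)
        assert suite[24].summarize().observed_arr == pytest.approx(0.20)
        assert suite[44].summarize().observed_arr == pytest.approx(0.0)

    def test_all_examples_share_one_apache_vector_with_identical_arm_moments(self, suite):
        ref = default_shared_apache()
        for ds in suite.values():
            np.testing.assert_array_equal(ds.df["apache"].to_numpy(), ref)
        pmx = ref[:100]
        ctl = ref[100:]
        assert pmx.mean() == pytest.approx(ctl.mean())
        assert pmx.std() == pytest.approx(ctl.std())

    def test_death_assignment_is_deterministic_and_nested(self):
        a = make_worked_example(33)
        b = make_worked_example(33)
        assert a.df.equals(b.df)
        # more deaths = strictly larger death set (same frailty ranking)
        d33 = set(np.flatnonzero(make_worked_example(33).df["death28"]))
        d37 = set(np.flatnonzero(make_worked_example(37).df["death28"]))
        assert d33 < d37

    def test_zero_death_arm_and_invalid_counts(self):
        ds = make_worked_example(0)
        s = ds.summarize()
        assert (s.deaths_pmx, s.deaths_ctrl) == (0, 22)
        with pytest.raises(ValueError):
            make_worked_example(101)
        with pytest.raises(ValueError):
            make_worked_example(-1)


class TestMarginalIntercept:
    def test_no_covariate_effect_reduces_to_logit(self):
        cm = CovariateModel(effect_logor_per_point=0.0)
        a = solve_marginal_intercept(0.37, cm)
        assert a == pytest.approx(logit(0.37), abs=1e-9)

    def test_symmetric_covariate_gives_zero_intercept_at_half(self):
        # mean at the support midpoint: the discretized pmf is exactly symmetric
        cm = CovariateModel(mean=35.5, sd=7.0)
        assert solve_marginal_intercept(0.5, cm) == pytest.approx(0.0, abs=1e-8)

    def test_monte_carlo_oracle(self):
        cm = CovariateModel(mean=25.0, sd=7.0, effect_logor_per_point=0.1)
        a = solve_marginal_intercept(0.45, cm)
        rng = np.random.default_rng(2024)
        x = cm.sample(rng, 1_000_000)
        risks = expit(a + 0.1 * (x - cm.mean_score()))
        mc_se = risks.std() / np.sqrt(risks.size)
        assert abs(risks.mean() - 0.45) < 3 * mc_se

    def test_invalid_target_rejected(self, covariate_model):
        with pytest.raises(ValueError):
            solve_marginal_intercept(0.0, covariate_model)


class TestTrialSimulator:
    def test_arm_sizes_and_determinism(self, covariate_model):
        sc = Scenario(control_risk=0.5, arr=0.15)
        a = generate_trial_dataset(sc, covariate_model, seed=3)
        b = generate_trial_dataset(sc, covariate_model, seed=3)
        assert (a.n_pmx, a.n_ctrl) == (100, 50)
        assert a.df.equals(b.df)

    def test_impossible_risks_rejected(self, covariate_model):
        class Raw:  # bypasses Scenario's own validation on purpose
            control_risk, arr, n_pmx, n_ctrl = 0.3, 0.4, 100, 50

        with pytest.raises(ValueError):
            generate_trial_dataset(Raw(), covariate_model, seed=0)
        with pytest.raises(ValueError):
            Scenario(control_risk=0.3, arr=0.4)

    def test_marginal_rates_converge_to_scenario_targets(self, covariate_model):
        sc = Scenario(control_risk=0.50, arr=0.15)
        reps = 10_000
        deaths_pmx = deaths_ctl = 0
        for r in range(reps):
            ds = generate_trial_dataset(sc, covariate_model, seed=np.random.default_rng([5, r]))
            s = ds.summarize()
            deaths_pmx += s.deaths_pmx
            deaths_ctl += s.deaths_ctrl
        rate_pmx = deaths_pmx / (reps * 100)
        rate_ctl = deaths_ctl / (reps * 50)
        se_pmx = np.sqrt(0.35 * 0.65 / (reps * 100))
        se_ctl = np.sqrt(0.50 * 0.50 / (reps * 50))
        assert abs(rate_pmx - 0.35) < 3 * se_pmx
        assert abs(rate_ctl - 0.50) < 3 * se_ctl


def test_dataset_csv_round_trip(tmp_path, cohort):
    path = tmp_path / "cohort.csv"
    cohort.to_csv(path)
    back = TrialDataset.from_csv(path)
    assert back.df.equals(cohort.df)
    assert back.label == cohort.label
    assert back.source == cohort.source


def test_dataset_validation_rejects_bad_records(cohort):
    bad = cohort.df.copy()
    bad.loc[0, "apache"] = 99
    with pytest.raises(ValueError):
        TrialDataset(df=bad)
    bad2 = cohort.df.copy()
    bad2.loc[0, "death28"] = 2
    with pytest.raises(ValueError):
        TrialDataset(df=bad2)
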
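"""Power-prior, normalized-power-prior and commensurate-prior behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

from histborrow.cohorts import TrialDataset
from histborrow.likelihoods import Parameters, log_likelihood
from histborrow.posterior import fit_posterior
from histborrow.priors import (PriorSpec, base_log_prior, effective_prior_weight,
                               historical_beta_marginal,
                               joint_log_posterior_kernel,
                               log_power_prior_normalizer)


@pytest.fixture(scope="module")
def null_summary(suite):
    return suite[44].summarize()


class TestFixedWeightIdentities:
    def test_zero_weight_kernel_equals_no_borrowing(self, null_summary,
                                                    cohort_summary, unadj):
        none_spec = PriorSpec(kind="none")
        zero_spec = PriorSpec(kind="fixed_weight", a0=0.0, historical=cohort_summary)
        rng = np.random.default_rng(1)
        for _ in range(5):
            p = Parameters(*rng.normal(0, 1, 2))
            assert joint_log_posterior_kernel(p, zero_spec, null_summary, unadj) == \
                pytest.approx(joint_log_posterior_kernel(p, none_spec, null_summary,
                                                         unadj), abs=1e-12)

    def test_unit_weight_posterior_equals_pooled_dataset_analysis(
            self, suite, cohort, null_summary, cohort_summary, unadj):
        pooled = TrialDataset(
            df=pd.concat([cohort.df, suite[44].df], ignore_index=True))
        via_prior = fit_posterior(null_summary,
                                  PriorSpec(kind="fixed_weight", a0=1.0,
                                            historical=cohort_summary), unadj)
        via_pooling = fit_posterior(pooled.summarize(), PriorSpec(kind="none"), unadj)
        assert via_prior.pr_benefit == pytest.approx(via_pooling.pr_benefit, abs=1e-6)
        assert via_prior.or_median == pytest.approx(via_pooling.or_median, abs=1e-6)


class TestPowerPriorNormalizer:
    def test_zero_exponent_integrates_the_base_prior_to_one(self, cohort_summary, unadj):
        assert log_power_prior_normalizer(0.0, cohort_summary, unadj) == \
            pytest.approx(0.0, abs=1e-6)

    def test_log_normalizer_is_convex_in_the_exponent(self, cohort_summary, unadj):
        grid = np.linspace(0.0, 1.0, 9)
        vals = [log_power_prior_normalizer(a, cohort_summary, unadj) for a in grid]
        second_diff = np.diff(vals, 2)
        assert np.all(second_diff > -1e-6)

    def test_unit_exponent_matches_monte_carlo_marginal_likelihood(
            self, cohort_summary, unadj):
        """C(1) is the historical marginal likelihood under the base prior."""
        logc = log_power_prior_normalizer(1.0, cohort_summary, unadj)
        rng = np.random.default_rng(11)
        n = 1_000_000
        draws = rng.normal(0.0, 10.0, size=(n, 2))
        ll = np.array([0.0])
        # vectorized unadjusted log-likelihood at each prior draw
        a, b = draws[:, 0], draws[:, 1]
        s = cohort_summary
        ll = (s.deaths_ctrl * a - s.n_ctrl * np.logaddexp(0, a)
              + s.deaths_pmx * (a + b) - s.n_pmx * np.logaddexp(0, a + b))
        log_est = logsumexp(ll) - np.log(n)
        # delta-method MC standard error of the log estimate
        w = np.exp(ll - ll.max())
        se_log = w.std() / (w.mean() * np.sqrt(n))
        assert abs(log_est - logc) < 3 * se_log

    def test_exponent_outside_unit_interval_rejected(self, cohort_summary, unadj):
        with pytest.raises(ValueError):
            log_power_prior_normalizer(1.5, cohort_summary, unadj)


class TestCommensurateLimits:
    def test_small_tau_approaches_full_pooling_of_the_treatment_effect(
            self, suite, cohort, null_summary, cohort_summary, unadj):
        tight = fit_posterior(null_summary,
                              PriorSpec(kind="commensurate", historical=cohort_summary,
                                        tau_fixed=1e-4), unadj)
        pooled = fit_posterior(null_summary,
                               PriorSpec(kind="fixed_weight", a0=1.0,
                                         historical=cohort_summary), unadj)
        # separate intercepts remain, so agreement is close but not exact
        assert abs(tight.pr_benefit - pooled.pr_benefit) < 0.02
        assert tight.or_median == pytest.approx(pooled.or_median, abs=0.05)

    def test_large_tau_approaches_no_borrowing(self, null_summary, cohort_summary, unadj):
        loose = fit_posterior(null_summary,
                              PriorSpec(kind="commensurate", historical=cohort_summary,
                                        tau_fixed=1e4), unadj)
        none = fit_posterior(null_summary, PriorSpec(kind="none"), unadj)
        assert abs(loose.pr_benefit - none.pr_benefit) < 0.005
        assert loose.or_median == pytest.approx(none.or_median, abs=0.02)

    def test_marginalized_engine_matches_full_hierarchy_quadrature(
            self, null_summary, cohort_summary, unadj):
        """Independent oracle: integrate the full (alpha_h, beta_h, alpha_n,
        beta_n) hierarchy at fixed tau on a dense product grid and compare the
        beta_n marginal with the engine's marginalized commensurate fit."""
        tau = 0.3
        sd = 10.0
        ah = np.linspace(-1.5, 1.0, 51)
        bh = np.linspace(-2.5, 1.5, 101)
        an = np.linspace(-1.5, 1.0, 51)
        bn = np.linspace(-2.5, 1.5, 101)

        def ll2(s, alpha, beta):
            return (s.deaths_ctrl * alpha - s.n_ctrl * np.logaddexp(0, alpha)
                    + s.deaths_pmx * (alpha + beta)
                    - s.n_pmx * np.logaddexp(0, alpha + beta))

        lh = ll2(cohort_summary, ah[:, None], bh[None, :])
        ln = ll2(null_summary, an[:, None], bn[None, :])
        link = (-0.5 * ((bn[None, :] - bh[:, None]) / tau) ** 2
                - np.log(tau) - 0.5 * np.log(2 * np.pi))
        prior = (base_log_prior(sd, ah)[:, None, None, None]
                 + base_log_prior(sd, bh)[None, :, None, None]
                 + base_log_prior(sd, an)[None, None, :, None])
        logk = (prior + lh[:, :, None, None] + ln[None, None, :, :]
                + link[None, :, None, :])
        dens = np.exp(logk - logk.max())
        for axis, grid in ((2, an), (1, bh), (0, ah)):
            dens = np.trapezoid(dens, grid, axis=axis)
        dens /= np.trapezoid(dens, bn)
        cdf = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(bn))])
        pr_oracle = np.interp(0.0, bn, cdf / cdf[-1])
        med_oracle = np.exp(np.interp(0.5, cdf / cdf[-1], bn))

        fit = fit_posterior(null_summary,
                            PriorSpec(kind="commensurate", historical=cohort_summary,
                                      tau_fixed=tau), unadj)
        assert fit.pr_benefit == pytest.approx(pr_oracle, abs=0.003)
        assert fit.or_median == pytest.approx(med_oracle, abs=0.01)

        # the hierarchical kernel API agrees with the oracle's integrand
        spec = PriorSpec(kind="commensurate", historical=cohort_summary, tau_fixed=tau)
        i, j, k, m = 20, 50, 20, 50
        val = joint_log_posterior_kernel(
            Parameters(an[k], bn[m]), spec, null_summary, unadj,
            hist_params=Parameters(ah[i], bh[j]), tau=tau)
        s_tau = spec.tau_scale
        tau_hyper = 0.5 * np.log(2 / np.pi) - np.log(s_tau) - 0.5 * (tau / s_tau) ** 2
        assert val == pytest.approx(float(logk[i, j, k, m]) + tau_hyper, abs=1e-8)


class TestHistoricalMarginal:
    def test_marginal_is_a_proper_density_peaked_at_the_historical_effect(
            self, cohort_summary, unadj):
        grid, dens = historical_beta_marginal(cohort_summary, unadj)
        mass = np.trapezoid(dens, grid)
        assert mass == pytest.approx(1.0, abs=1e-8)
        mode = grid[np.argmax(dens)]
        # historical log-OR: log((33/57)/(42/47)) ~ -0.434
        assert mode == pytest.approx(np.log((33 / 57) / (42 / 47)), abs=0.02)


class TestEffectiveWeight:
    def test_boundary_targets_return_the_envelope_endpoints(
            self, null_summary, cohort_summary, unadj):
        pr_none = fit_posterior(null_summary, PriorSpec(kind="none"), unadj).pr_benefit
        res = effective_prior_weight(null_summary, pr_none - 0.05, unadj, cohort_summary)
        assert res.at_boundary and res.a0_star == 0.0
        pr_full = fit_posterior(null_summary,
                                PriorSpec(kind="fixed_weight", a0=1.0,
                                          historical=cohort_summary), unadj).pr_benefit
        res = effective_prior_weight(null_summary, pr_full + 0.05, unadj, cohort_summary)
        assert res.at_boundary and res.a0_star == 1.0

    def test_interior_target_is_recovered(self, null_summary, cohort_summary, unadj):
        pr_half = fit_posterior(null_summary,
                                PriorSpec(kind="fixed_weight", a0=0.5,
                                          historical=cohort_summary), unadj).pr_benefit
        res = effective_prior_weight(null_summary, pr_half, unadj, cohort_summary)
        assert not res.at_boundary
        assert res.a0_star == pytest.approx(0.5, abs=0.05)


class TestMonotonicityInWeight:
    def test_null_example_probability_increases_with_borrowing(
            self, null_summary, cohort_summary, unadj):
        prs = []
        for a0 in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = PriorSpec(kind="none") if a0 == 0 else \
                PriorSpec(kind="fixed_weight", a0=a0, historical=cohort_summary)
            prs.append(fit_posterior(null_summary, spec, unadj).pr_benefit)
        assert np.all(np.diff(prs) > 0)


class TestPriorSpecValidation:
    def test_required_fields_by_kind(self, cohort_summary):
        with pytest.raises(ValueError):
            PriorSpec(kind="fixed_weight", historical=cohort_summary)  # missing a0
        with pytest.raises(ValueError):
            PriorSpec(kind="fixed_weight", a0=1.2, historical=cohort_summary)
        with pytest.raises(ValueError):
            PriorSpec(kind="commensurate")  # missing historical
        with pytest.raises(ValueError):
            PriorSpec(kind="meta_analytic")

    def test_serialization_round_trip(self, cohort_summary):
        spec = PriorSpec(kind="fixed_weight", a0=0.75, historical=cohort_summary)
        back = PriorSpec.from_dict(spec.to_dict(), historical=cohort_summary)
        assert back.kind == spec.kind and back.a0 == spec.a0
        none_back = PriorSpec.from_dict(PriorSpec(kind="none").to_dict())
        assert none_back.kind == "none"
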
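import numpy as np
import pytest

from snpreclass import (
    FamilyHistoryAdjustment,
    RiskBin,
    RiskDistribution,
    bcsc_screening_marginals,
    fit_smooth_distribution,
    read_risk_distribution,
    sample_cohort,
    write_risk_distribution,
)
from snpreclass.population import LognormalRiskFit


class TestCoarseMarginals:
    def test_bin_edges_and_raw_masses(self):
        dist = bcsc_screening_marginals()
        assert len(dist) == 7
        b = dist.bins[5]
        assert (b.lower, b.upper) == (0.03, 0.04)
        assert b.mass == pytest.approx(0.046)
        assert np.isinf(dist.bins[6].upper)

    def test_mass_above_treatment_threshold_before_normalisation(self):
        dist = bcsc_screening_marginals()
        assert dist.mass_above(0.03, normalized=False) == pytest.approx(0.069)

    def test_normalisation_absorbs_rounding_slack(self):
        dist = bcsc_screening_marginals()
        assert dist.total_mass == pytest.approx(1.001)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.normalized().total_mass == pytest.approx(1.0, abs=1e-12)


class TestRiskDistribution:
    def test_non_contiguous_bins_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            RiskDistribution([RiskBin(0.0, 0.01, 0.5), RiskBin(0.02, 0.03, 0.5)])

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            RiskBin(0.02, 0.01, 0.1)
        with pytest.raises(ValueError):
            RiskBin(0.01, 0.02, -0.1)

    def test_file_round_trip_including_open_top_bin(self, tmp_path):
        dist = bcsc_screening_marginals()
        path = tmp_path / "dist.csv"
        write_risk_distribution(dist, path)
        back = read_risk_distribution(path)
        np.testing.assert_allclose(back.masses, dist.masses)
        np.testing.assert_allclose(back.lowers, dist.lowers)
        assert np.isinf(back.uppers[-1])


class TestLognormalFit:
    def test_parameter_recovery_from_known_lognormal(self):
        """Refit on marginals generated by a known lognormal recovers it."""
        true = LognormalRiskFit(mu=-4.3, sigma=0.75)
        edges = bcsc_screening_marginals()
        masses = true.bin_masses(edges.lowers, edges.uppers)
        marginals = RiskDistribution(
            RiskBin(lo, up, m) for lo, up, m in zip(edges.lowers, edges.uppers, masses)
        )
        fit = fit_smooth_distribution(marginals)
        assert fit.mu == pytest.approx(true.mu, rel=0.05)
        assert fit.sigma == pytest.approx(true.sigma, rel=0.05)

    def test_fit_quality_on_coarse_marginals(self):
        """Residuals at the global least-squares optimum of the 2-parameter
        lognormal on the coarse marginals: worst bin 1.63 pp, tail mass
        above 3% off by 0.0134 (frozen from an exhaustive global search).
        """
        fit = fit_smooth_distribution(bcsc_screening_marginals())
        assert np.abs(fit.residuals).max() < 0.017
        target_tail = bcsc_screening_marginals().mass_above(0.03)
        assert fit.sf(0.03) == pytest.approx(target_tail, abs=0.014)

    def test_tail_is_strictly_decreasing(self):
        fit = fit_smooth_distribution(bcsc_screening_marginals())
        grid = np.linspace(0.001, 0.25, 100)
        assert np.all(np.diff(fit.sf(grid)) < 0)

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError, match="3 bins"):
            fit_smooth_distribution(RiskDistribution([RiskBin(0.0, 0.05, 1.0)]))


class TestSampleCohort:
    def test_reproducible_given_seed(self, reference_panel):
        dist = bcsc_screening_marginals()
        a = sample_cohort(dist, 2000, reference_panel, seed=5)
        b = sample_cohort(dist, 2000, reference_panel, seed=5)
        np.testing.assert_array_equal(a.prior, b.prior)
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
        np.testing.assert_array_equal(a.posterior, b.posterior)

    def test_null_panel_posterior_equals_prior(self, null_panel):
        cohort = sample_cohort(bcsc_screening_marginals(), 5000, null_panel, fh_rate=0.0, seed=1)
        np.testing.assert_allclose(cohort.posterior, cohort.prior, atol=1e-12)
        np.testing.assert_allclose(cohort.log_lr, 0.0, atol=1e-12)

    def test_posterior_consistent_with_prior_and_log_lr(self, reference_panel):
        cohort = sample_cohort(
            bcsc_screening_marginals(), 5000, reference_panel, fh_rate=0.0, seed=3
        )
        odds = cohort.prior / (1 - cohort.prior) * np.exp(cohort.log_lr)
        np.testing.assert_allclose(cohort.posterior, odds / (1 + odds), atol=1e-12)

    def test_empirical_bin_masses_match_input(self, reference_panel):
        n = 200_000
        dist = bcsc_screening_marginals()
        cohort = sample_cohort(dist, n, reference_panel, fh_rate=0.0, seed=11)
        probs = dist.probabilities
        edges = np.append(dist.lowers, np.inf)
        counts, _ = np.histogram(cohort.prior, edges)
        emp = counts / n
        se = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(emp - probs) < 3.5 * se)

    def test_mean_posterior_conserves_mean_prior_without_fh(self, reference_panel):
        cohort = sample_cohort(
            bcsc_screening_marginals(), 200_000, reference_panel, fh_rate=0.0, seed=17
        )
        assert cohort.posterior.mean() == pytest.approx(cohort.prior.mean(), rel=0.02)

    def test_population_mean_lr_near_one_without_fh(self, reference_panel):
        cohort = sample_cohort(
            bcsc_screening_marginals(), 100_000, reference_panel, fh_rate=0.0, seed=19
        )
        lr = np.exp(cohort.log_lr)
        se = lr.std() / np.sqrt(lr.size)
        # population mean LR sits a hair above 1 (prevalence-order term)
        assert lr.mean() == pytest.approx(1.0, abs=3 * se + 0.01)

    def test_fh_rate_controls_flag_prevalence(self, reference_panel):
        cohort = sample_cohort(
            bcsc_screening_marginals(), 50_000, reference_panel, fh_rate=0.114, seed=23
        )
        se = np.sqrt(0.114 * 0.886 / 50_000)
        assert cohort.fh_positive.mean() == pytest.approx(0.114, abs=3.5 * se)

    def test_fh_positive_subjects_score_stochastically_higher(self, reference_panel):
        from scipy.stats import mannwhitneyu

        cohort = sample_cohort(
            bcsc_screening_marginals(), 50_000, reference_panel, fh_rate=0.5, seed=29
        )
        fh = cohort.log_lr[cohort.fh_positive]
        no = cohort.log_lr[~cohort.fh_positive]
        res = mannwhitneyu(fh, no, alternative="greater")
        assert res.pvalue < 1e-6

    def test_top_bin_draws_stay_below_cap(self, reference_panel):
        cohort = sample_cohort(
            bcsc_screening_marginals(), 50_000, reference_panel, fh_rate=0.0, seed=31
        )
        top = cohort.prior[cohort.prior >= 0.04]
        assert top.size > 0
        assert np.all(top <= 0.30)

    def test_invalid_rates_rejected(self, reference_panel):
        with pytest.raises(ValueError):
            sample_cohort(bcsc_screening_marginals(), 10, reference_panel, fh_rate=1.5, seed=1)
        with pytest.raises(ValueError):
            sample_cohort(bcsc_screening_marginals(), 0, reference_panel, seed=1)
        with pytest.raises(ValueError):
            FamilyHistoryAdjustment(2.0, -0.1)
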
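import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpreclass import (
    FamilyHistoryAdjustment,
    SnpPanel,
    SnpRecord,
    estimate_proportion_explained,
    fh_adjusted_posterior,
    genotype_dist,
    log_panel_lr,
    panel_lr,
    posterior_risk,
    snp_lr,
)
from snpreclass.genotypes import PanelGenotypeModel


class TestSnpLr:
    def test_homozygote_value_hand_arithmetic(self, single_snp):
        dist = genotype_dist(single_snp, prevalence=0.05)
        # 0.1153435 / 0.0886661 from the case/control triples
        assert snp_lr(2, dist) == pytest.approx(1.3009, abs=1e-3)

    def test_null_snp_gives_unit_lr_everywhere(self):
        dist = genotype_dist(SnpRecord("n", 0.4, 1.0), prevalence=0.05)
        for g in (0, 1, 2):
            assert snp_lr(g, dist) == pytest.approx(1.0, abs=1e-14)

    @settings(max_examples=100, deadline=None)
    @given(p=st.floats(0.01, 0.99), gamma=st.floats(1.0, 2.0), k=st.floats(0.001, 0.10))
    def test_expected_lr_over_controls_is_one_exactly(self, p, gamma, k):
        dist = genotype_dist(SnpRecord("x", p, gamma), prevalence=k)
        expectation = sum(dist.probs_controls[g] * snp_lr(g, dist) for g in range(3))
        assert expectation == pytest.approx(1.0, abs=1e-12)

    def test_invalid_genotype_count_rejected(self, single_snp):
        with pytest.raises(ValueError):
            snp_lr(3, genotype_dist(single_snp))


class TestPanelLr:
    def test_null_panel_product_is_one(self, null_panel):
        model = PanelGenotypeModel(null_panel)
        assert panel_lr(np.array([0, 1, 2]), model) == pytest.approx(1.0, abs=1e-12)

    def test_two_snp_product_equals_per_snp_product(self):
        panel = SnpPanel([SnpRecord("a", 0.3, 1.2), SnpRecord("b", 0.15, 1.4)])
        model = PanelGenotypeModel(panel)
        for g in ([0, 0], [1, 2], [2, 1]):
            expected = snp_lr(g[0], model.dists[0]) * snp_lr(g[1], model.dists[1])
            assert panel_lr(np.array(g), model) == pytest.approx(expected, rel=1e-12)

    def test_log_space_matches_naive_product_on_reference_panel(self, reference_panel, rng):
        model = PanelGenotypeModel(reference_panel)
        genotypes = rng.integers(0, 3, size=(1000, len(reference_panel)))
        log_lr = log_panel_lr(genotypes, model)
        lr_table = model.cases / model.controls
        naive = np.prod(lr_table[np.arange(len(reference_panel)), genotypes], axis=1)
        np.testing.assert_allclose(np.exp(log_lr), naive, rtol=1e-9)

    def test_length_mismatch_rejected(self, reference_panel):
        model = PanelGenotypeModel(reference_panel)
        with pytest.raises(ValueError, match="panel"):
            panel_lr(np.zeros(3, dtype=int), model)


class TestPosteriorRisk:
    def test_unit_lr_is_identity(self):
        assert posterior_risk(0.03, 1.0) == pytest.approx(0.03, abs=1e-15)

    def test_hand_arithmetic(self):
        # odds 0.02/0.98 * 2 = 0.0408163 -> 0.0408163/1.0408163
        assert posterior_risk(0.02, 2.0) == pytest.approx(0.039216, abs=1e-6)

    def test_monotone_in_lr_and_prior(self):
        priors = np.linspace(0.005, 0.2, 25)
        assert np.all(posterior_risk(priors, 2.0) > posterior_risk(priors, 1.5))
        assert np.all(np.diff(posterior_risk(priors, 1.3)) > 0)

    @pytest.mark.parametrize("prior", [0.0, 1.0, -0.2, 1.3])
    def test_prior_outside_open_interval_rejected(self, prior):
        with pytest.raises(ValueError):
            posterior_risk(prior, 1.5)

    @settings(max_examples=200, deadline=None)
    @given(prior=st.floats(1e-6, 1 - 1e-6), lr=st.floats(1e-3, 1e3))
    def test_odds_update_round_trip_recovers_prior(self, prior, lr):
        """posterior -> odds -> divide by LR -> risk inverts the update."""
        post = posterior_risk(prior, lr)
        back_odds = post / (1.0 - post) / lr
        assert back_odds / (1.0 + back_odds) == pytest.approx(prior, abs=1e-12)


class TestFamilyHistoryAdjustment:
    def test_zero_proportion_reduces_to_plain_posterior(self):
        adj = FamilyHistoryAdjustment(2.0, 0.0)
        for prior, lr in [(0.01, 0.7), (0.05, 1.8), (0.2, 1.0)]:
            assert fh_adjusted_posterior(prior, lr, adj) == posterior_risk(prior, lr)

    def test_deflates_prior_odds_by_stated_power(self):
        adj = FamilyHistoryAdjustment(2.0, 0.3)
        prior = 0.06
        post = fh_adjusted_posterior(prior, 1.0, adj)
        post_odds = post / (1 - post)
        assert post_odds == pytest.approx(prior / (1 - prior) / 2.0**0.3, rel=1e-12)

    def test_invalid_fields_rejected(self):
        with pytest.raises(ValueError):
            FamilyHistoryAdjustment(0.5, 0.2)
        with pytest.raises(ValueError):
            FamilyHistoryAdjustment(2.0, 1.2)

    def test_fh_conditioned_average_restores_prior(self, reference_panel):
        """Deflation cancels the expected LR uplift of FH+ genotypes.

        Exact on the odds scale; the probability scale carries only the
        small Jensen gap from odds -> probability curvature.
        """
        pi = estimate_proportion_explained(reference_panel, 2.0, 0.05)
        adj = FamilyHistoryAdjustment(2.0, pi)
        model = PanelGenotypeModel(reference_panel)
        rng = np.random.default_rng(7)
        lr = np.exp(model.score(model.draw("fh", 100_000, rng)))
        deflated = lr / adj.odds_deflator
        se = deflated.std() / np.sqrt(deflated.size)
        assert deflated.mean() == pytest.approx(1.0, abs=4 * se)
        prior = 0.04
        post = fh_adjusted_posterior(prior, lr, adj)
        assert post.mean() == pytest.approx(prior, rel=0.02)


class TestProportionExplained:
    def test_null_panel_explains_nothing(self, null_panel):
        assert estimate_proportion_explained(null_panel, 2.0) == 0.0

    def test_clamped_to_unit_interval(self, reference_panel):
        # a barely-familial RR forces the raw ratio above 1
        assert estimate_proportion_explained(reference_panel, 1.0 + 1e-9) == 1.0
        pi = estimate_proportion_explained(reference_panel, 2.0)
        assert 0.0 < pi < 1.0

    def test_monotone_in_panel_effect_sizes(self, reference_panel):
        values = [
            estimate_proportion_explained(reference_panel.scaled(f), 2.0)
            for f in (0.5, 1.0, 1.5, 2.0)
        ]
        assert np.all(np.diff(values) > 0)

    def test_requires_familial_excess_risk(self, reference_panel):
        with pytest.raises(ValueError):
            estimate_proportion_explained(reference_panel, 1.0)


def test_mean_log_lr_symmetric_between_arms(reference_panel, rng):
    """Cases score above zero, controls below, near-symmetrically."""
    model = PanelGenotypeModel(reference_panel)
    cases = model.score(model.draw("case", 100_000, rng))
    controls = model.score(model.draw("control", 100_000, rng))
    assert cases.mean() > 0 > controls.mean()
    se = np.hypot(cases.std(), controls.std()) / np.sqrt(100_000)
    assert cases.mean() + controls.mean() == pytest.approx(0.0, abs=4 * se + 0.005)


def test_empirical_panel_lr_mean_is_one_over_controls(reference_panel, rng):
    model = PanelGenotypeModel(reference_panel)
    lr = np.exp(model.score(model.draw("control", 100_000, rng)))
    se = lr.std() / np.sqrt(lr.size)
    assert lr.mean() == pytest.approx(1.0, abs=3 * se)
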
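"""Generator checks: design-factor sampling, thresholding, bot rows, ground truth."""

import numpy as np
import pytest
from scipy.stats import chisquare, norm

from botclass.simulate import (
    SimulationDesign,
    build_true_parameters,
    generate_bot_responses,
    generate_dataset,
    generate_human_responses,
    observed_metric_attenuation,
    sample_design_factors,
)


class TestDesignFactors:
    def test_uniform_moments(self, rng):
        design = SimulationDesign(seed=0)
        draws = np.array([sample_design_factors(design, rng)[0]
                          for _ in range(100_000)])
        lo, hi = design.communality_mean_range
        mc_se = (hi - lo) / np.sqrt(12 * draws.size)
        assert abs(draws.mean() - (lo + hi) / 2) < 3 * mc_se

    def test_degenerate_interval_returns_constant(self, rng):
        design = SimulationDesign(communality_mean_range=(0.3, 0.3))
        assert sample_design_factors(design, rng)[0] == 0.3

    def test_rho_support(self, rng):
        design = SimulationDesign()
        rhos = np.array([sample_design_factors(design, rng)[1]
                         for _ in range(10_000)])
        assert rhos.min() >= 0.0 and rhos.max() <= 0.7


class TestTrueParameters:
    def test_zero_halfwidth_forces_loadings(self, rng):
        design = SimulationDesign(communality_halfwidth=0.0)
        params = build_true_parameters(design, 0.5, 0.2, rng)
        assert np.allclose(params.loadings_std, np.sqrt(0.5))
        assert np.allclose(params.residual_variances, 0.5)

    def test_zero_rho_gives_identity(self, rng):
        params = build_true_parameters(SimulationDesign(), 0.4, 0.0, rng)
        assert np.allclose(params.factor_cov, np.eye(3))

    def test_unit_item_variance_identity(self, rng):
        params = build_true_parameters(SimulationDesign(), 0.3, 0.5, rng)
        assert np.allclose(params.loadings_std ** 2 + params.residual_variances, 1.0)

    def test_communality_mean_recovered(self, rng):
        design = SimulationDesign(n_factors=1, items_per_factor=10_000)
        params = build_true_parameters(design, 0.25, 0.0, rng)
        h2 = params.loadings_std ** 2
        mc_se = 0.30 / np.sqrt(12 * h2.size)
        assert abs(h2.mean() - 0.25) < 3 * mc_se

    def test_simple_structure(self, rng):
        params = build_true_parameters(SimulationDesign(), 0.4, 0.3, rng)
        assert (np.count_nonzero(params.loading_matrix, axis=1) == 1).all()


class TestHumanResponses:
    def test_category_marginals_match_normal_cells(self, rng):
        design = SimulationDesign(communality_mean_range=(0.5, 0.5),
                                  communality_halfwidth=0.0)
        params = build_true_parameters(design, 0.5, 0.3, rng)
        y = generate_human_responses(params, 100_000, design.thresholds, rng)
        # the latent response is standard normal, so cell probabilities are
        # normal CDF differences at the thresholds
        p2 = norm.cdf(-1) - norm.cdf(-2)
        freq2 = np.mean(y == 2)
        mc_se = np.sqrt(p2 * (1 - p2) / y.size)
        assert abs(freq2 - p2) < 3 * mc_se
        assert y.min() >= 1 and y.max() <= 6

    def test_within_factor_correlation_matches_attenuated_value(self, rng):
        design = SimulationDesign(communality_mean_range=(0.5, 0.5),
                                  communality_halfwidth=0.0)
        params = build_true_parameters(design, 0.5, 0.0, rng)
        y = generate_human_responses(params, 200_000, design.thresholds, rng)
        r_obs = np.corrcoef(y[:, 0], y[:, 1])[0, 1]
        att = observed_metric_attenuation(design.thresholds, 6)
        assert abs(r_obs - att ** 2 * 0.5) < 0.01


class TestBotResponses:
    def test_uniform_frequencies(self, rng):
        y = generate_bot_responses(20_000, 5, 6, rng)
        freqs = np.bincount(y.ravel(), minlength=7)[1:] / y.size
        mc_se = np.sqrt((1 / 6) * (5 / 6) / y.size)
        assert np.all(np.abs(freqs - 1 / 6) < 4 * mc_se)

    def test_empty(self, rng):
        assert generate_bot_responses(0, 18, 6, rng).shape == (0, 18)

    def test_chisquare_gof_not_rejected(self, rng):
        y = generate_bot_responses(20_000, 5, 6, rng)
        counts = np.bincount(y.ravel(), minlength=7)[1:]
        assert chisquare(counts).pvalue > 0.001

    def test_row_moments(self, rng):
        y = generate_bot_responses(50_000, 6, 6, rng)
        assert abs(y.mean() - 3.5) < 0.02
        assert abs(y.var() - 35 / 12) < 0.05


class TestGenerateDataset:
    def test_exact_bot_count(self):
        _, truth = generate_dataset(SimulationDesign(n_persons=400,
                                                     prop_bots=0.25, seed=1))
        assert truth.n_bots == 100

    def test_zero_contamination(self):
        _, truth = generate_dataset(SimulationDesign(prop_bots=0.0, seed=2))
        assert truth.n_bots == 0

    def test_seed_reproducibility(self):
        d = SimulationDesign(seed=9)
        data1, truth1 = generate_dataset(d)
        data2, truth2 = generate_dataset(d)
        assert np.array_equal(data1.responses, data2.responses)
        assert np.array_equal(truth1.class_labels, truth2.class_labels)

    def test_labels_aligned_after_shuffle(self):
        data, truth = generate_dataset(
            SimulationDesign(n_persons=600, prop_bots=0.5, seed=3))
        rowvar = data.responses.var(axis=1)
        # uniform random rows are more variable than content-driven rows
        assert (rowvar[truth.class_labels == "bot"].mean()
                > rowvar[truth.class_labels == "human"].mean())

    def test_rounded_zero_warns(self):
        with pytest.warns(UserWarning):
            generate_dataset(SimulationDesign(n_persons=100, prop_bots=0.001,
                                              seed=4))

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(prop_bots=1.5)
        with pytest.raises(ValueError):
            SimulationDesign(thresholds=(1.0, 0.5, 2.0, 3.0, 4.0))
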
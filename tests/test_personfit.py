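"""Person-fit index and variability index: oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from botclass.datasets import SurveyDataset
from botclass.personfit import (
    CfaMlFit,
    PersonIndices,
    fit_ml_cfa,
    individual_loglik,
    person_fit_y1,
    standardize_indices,
    variability_y2,
)


def _dataset(y, fmap):
    return SurveyDataset(responses=np.asarray(y), item_factor_map=np.asarray(fmap))


class TestIndividualLoglik:
    def test_standard_normal_at_mode(self):
        val = individual_loglik(np.array([0.0]), np.array([0.0]), np.array([[1.0]]))
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_bivariate_identity(self):
        val = individual_loglik(np.array([1.0, 1.0]), np.zeros(2), np.eye(2))
        assert val == pytest.approx(-(np.log(2 * np.pi) + 1.0), abs=1e-12)

    def test_zero_mahalanobis(self, rng):
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        y = rng.standard_normal(2)
        val = individual_loglik(y, y, cov)
        expected = -0.5 * (2 * np.log(2 * np.pi) + np.log(np.linalg.det(cov)))
        assert val == pytest.approx(expected, abs=1e-10)

    def test_singular_cov_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            individual_loglik(np.zeros(2), np.zeros(2), np.ones((2, 2)))


class TestMlCfa:
    def test_recovery_on_clean_data(self, clean_dataset):
        data, truth = clean_dataset
        fit = fit_ml_cfa(data)
        assert fit.converged
        # standardized loadings must recover the attenuated population values
        lstd = np.array([
            fit.loadings[j, k] * np.sqrt(fit.factor_cov[k, k])
            / np.sqrt(fit.loadings[j, k] ** 2 * fit.factor_cov[k, k]
                      + fit.residual_variances[j])
            for j, k in enumerate(data.item_factor_map)])
        assert np.allclose(lstd, truth.loadings_std_observed, atol=0.05)

    def test_implied_cov_structure_identity(self, small_dataset):
        data, _ = small_dataset
        fit = fit_ml_cfa(data)
        recon = (fit.loadings @ fit.factor_cov @ fit.loadings.T
                 + np.diag(fit.residual_variances))
        assert np.allclose(recon, fit.implied_cov, atol=1e-12)

    def test_saturated_mean(self, small_dataset):
        data, _ = small_dataset
        fit = fit_ml_cfa(data)
        assert np.allclose(fit.implied_mean, data.responses.mean(axis=0))


class TestPersonFitY1:
    def test_zero_when_moments_equal(self, small_dataset):
        data, _ = small_dataset
        y = data.responses.astype(float)
        ybar, S = y.mean(axis=0), np.cov(y, rowvar=False)
        fit = CfaMlFit(loadings=None, factor_cov=None, residual_variances=None,
                       implied_mean=ybar, implied_cov=S, sample_mean=ybar,
                       sample_cov=S, converged=True, loglik=0.0)
        assert np.allclose(person_fit_y1(data, fit), 0.0, atol=1e-10)

    def test_trace_identity(self, small_dataset):
        """sum(y1) = N(ln|Sigma|-ln|S|) + sum D2(mu,Sigma) - p(N-1)."""
        data, _ = small_dataset
        fit = fit_ml_cfa(data)
        y1 = person_fit_y1(data, fit)
        y = data.responses.astype(float)
        n, p = y.shape
        r = y - fit.implied_mean
        d2_model = np.einsum("ij,ji->i", r, np.linalg.solve(fit.implied_cov, r.T))
        expected = (n * (np.log(np.linalg.det(fit.implied_cov))
                         - np.log(np.linalg.det(fit.sample_cov)))
                    + d2_model.sum() - p * (n - 1))
        assert y1.sum() == pytest.approx(expected, rel=1e-8)

    def test_direct_equals_algebraic_form(self, small_dataset):
        data, _ = small_dataset
        fit = fit_ml_cfa(data)
        y1 = person_fit_y1(data, fit)
        y = data.responses.astype(float)
        rm = y - fit.implied_mean
        rs = y - fit.sample_mean
        d2m = np.einsum("ij,ji->i", rm, np.linalg.solve(fit.implied_cov, rm.T))
        d2s = np.einsum("ij,ji->i", rs, np.linalg.solve(fit.sample_cov, rs.T))
        algebraic = (np.log(np.linalg.det(fit.implied_cov))
                     - np.log(np.linalg.det(fit.sample_cov)) + d2m - d2s)
        assert np.allclose(y1, algebraic, atol=1e-10)


class TestVariabilityY2:
    def test_constant_row_is_zero(self):
        data = _dataset(np.full((3, 6), 4), np.zeros(6, dtype=int))
        assert np.allclose(variability_y2(data), 0.0)

    def test_full_range_single_factor(self):
        data = _dataset([[1, 2, 3, 4, 5, 6]], np.zeros(6, dtype=int))
        assert variability_y2(data)[0] == pytest.approx(3.5)

    def test_uniform_bots_expectation(self, rng):
        from botclass.simulate import generate_bot_responses
        y = generate_bot_responses(20_000, 6, 6, rng)
        data = _dataset(y, np.zeros(6, dtype=int))
        y2 = variability_y2(data)
        mc_se = y2.std() / np.sqrt(y2.size)
        assert abs(y2.mean() - 35 / 12) < 3 * mc_se

    @settings(deadline=None, max_examples=20)
    @given(st.randoms(use_true_random=False))
    def test_invariant_to_item_and_factor_order(self, pyrandom):
        rng = np.random.default_rng(pyrandom.randrange(2**31))
        y = rng.integers(1, 7, size=(25, 12))
        fmap = np.repeat([0, 1], 6)
        base = variability_y2(_dataset(y, fmap))
        perm = np.concatenate([rng.permutation(6), 6 + rng.permutation(6)])
        shuffled = variability_y2(_dataset(y[:, perm], fmap[perm]))
        swapped = variability_y2(_dataset(y[:, ::-1], fmap[::-1]))
        assert np.allclose(base, shuffled, atol=1e-12)
        assert np.allclose(base, swapped, atol=1e-12)

    def test_single_item_factor_rejected(self):
        data = _dataset(np.ones((4, 3)), np.array([0, 0, 1]))
        with pytest.raises(ValueError, match="fewer than 2"):
            variability_y2(data)

    def test_bots_exceed_humans_on_synthetic_data(self):
        from botclass.simulate import SimulationDesign, generate_dataset
        for pb in (0.10, 0.25, 0.50):
            data, truth = generate_dataset(
                SimulationDesign(n_persons=400, prop_bots=pb, seed=21))
            y2 = variability_y2(data)
            assert (y2[truth.class_labels == "bot"].mean()
                    > y2[truth.class_labels == "human"].mean())


class TestStandardize:
    def test_zscores(self, rng):
        idx = PersonIndices(y1=rng.standard_normal(200) * 3 + 1,
                            y2=rng.standard_normal(200) * 0.2 + 5)
        out = standardize_indices(idx)
        assert abs(out.y1.mean()) < 1e-12 and abs(out.y1.std() - 1) < 1e-12
        assert out.standardized

    def test_idempotent(self, rng):
        idx = standardize_indices(PersonIndices(y1=rng.standard_normal(50),
                                                y2=rng.standard_normal(50)))
        again = standardize_indices(idx)
        assert np.allclose(idx.y1, again.y1, atol=1e-12)

    def test_constant_column_warns(self, rng):
        idx = PersonIndices(y1=rng.standard_normal(50), y2=np.full(50, 2.0))
        with pytest.warns(UserWarning, match="zero variance"):
            out = standardize_indices(idx)
        assert np.allclose(out.y2, 0.0)
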
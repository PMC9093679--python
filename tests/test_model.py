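"""Mixture model building blocks and small end-to-end fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import multivariate_normal, norm

from botclass.datasets import SurveyDataset
from botclass.model import (
    LatentClassCFA,
    McmcSettings,
    ModelSpec,
    PriorSettings,
    class_probability,
    classify_persons,
    mixture_loglik_person,
    standardized_loadings,
)


class TestClassProbability:
    def test_zero_coefficients(self):
        assert class_probability(1.3, -0.2, (0, 0, 0)) == 0.5

    def test_saturation(self):
        assert class_probability(0, 0, (30, 0, 0)) == pytest.approx(1.0, abs=1e-12)

    def test_hand_value(self):
        assert class_probability(2.0, 1.0, (0, 1, -1)) == pytest.approx(
            expit(1.0), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-20, 20), st.floats(-20, 20))
    def test_bounded(self, y1, y2):
        p = class_probability(y1, y2, (0.5, -1.2, 2.0))
        assert 0.0 <= p <= 1.0


class TestMixtureLoglik:
    spec = ModelSpec(item_factor_map=np.array([0, 0]))
    theta = dict(tau1=np.array([0.5, -0.2]), lam=np.array([1.0, 0.8]),
                 phi=np.array([[0.6]]), sigma1=np.array([0.5, 0.7]),
                 tau2=np.array([3.0, 3.2]), sigma2=np.array([2.5, 2.8]))
    y = np.array([1.2, 0.4])

    def _densities(self):
        lam = self.theta["lam"]
        cov1 = np.outer(lam, lam) * 0.6 + np.diag(self.theta["sigma1"])
        f1 = multivariate_normal.pdf(self.y, self.theta["tau1"], cov1)
        f2 = (norm.pdf(self.y[0], 3.0, np.sqrt(2.5))
              * norm.pdf(self.y[1], 3.2, np.sqrt(2.8)))
        return f1, f2

    def test_matches_two_term_brute_force(self):
        f1, f2 = self._densities()
        val = mixture_loglik_person(self.y, self.theta, 0.7, self.spec)
        assert val == pytest.approx(np.log(0.7 * f1 + 0.3 * f2), abs=1e-10)

    def test_mixture_collapse(self):
        f1, f2 = self._densities()
        assert mixture_loglik_person(self.y, self.theta, 1.0, self.spec) == \
            pytest.approx(np.log(f1), abs=1e-10)
        assert mixture_loglik_person(self.y, self.theta, 0.0, self.spec) == \
            pytest.approx(np.log(f2), abs=1e-10)

    def test_binary_family_against_quadrature(self):
        spec = ModelSpec(item_factor_map=np.array([0, 0]), family="binary")
        theta = dict(tau1=np.array([0.2, -0.3]), lam=np.array([1.0, 1.3]),
                     phi=np.array([[0.8]]), tau2=np.array([0.1, 0.0]))
        y = np.array([1.0, 0.0])

        def integrand(eta):
            pr = expit(theta["tau1"] + theta["lam"] * eta)
            return pr[0] * (1 - pr[1]) * norm.pdf(eta, 0, np.sqrt(0.8))

        f1 = quad(integrand, -10, 10)[0]
        f2 = expit(0.1) * (1 - expit(0.0))
        val = mixture_loglik_person(y, theta, 0.6, spec)
        assert val == pytest.approx(np.log(0.6 * f1 + 0.4 * f2), abs=1e-6)


class TestStandardizedLoadings:
    def test_hand_value(self):
        out = standardized_loadings(np.array([1.0]), np.array([0.5]),
                                    np.array([0.5]), np.array([0]))
        assert out[0] == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_zero_residual_limit(self):
        out = standardized_loadings(np.array([0.9]), np.array([1.0]),
                                    np.array([1e-12]), np.array([0]))
        assert out[0] == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="implied"):
            standardized_loadings(np.array([1.0]), np.array([-2.0]),
                                  np.array([0.5]), np.array([0]))


class _FakePosterior:
    def __init__(self, probs):
        self.bot_probability = np.asarray(probs)


class TestClassify:
    def test_threshold_rule_and_tie(self):
        out = classify_persons(_FakePosterior([0.9, 0.1, 0.5]), 0.5)
        assert list(out) == ["bot", "human", "human"]

    def test_monotone_in_threshold(self):
        probs = np.linspace(0.01, 0.99, 25)
        loose = set(np.flatnonzero(classify_persons(_FakePosterior(probs), 0.3) == "bot"))
        strict = set(np.flatnonzero(classify_persons(_FakePosterior(probs), 0.7) == "bot"))
        assert strict <= loose

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_persons(_FakePosterior([0.5]), 1.0)


class TestSettingsValidation:
    def test_burnin_must_be_shorter(self):
        with pytest.raises(ValueError):
            McmcSettings(n_iter=100, n_burnin=100)

    def test_two_chains_required(self):
        with pytest.raises(ValueError):
            McmcSettings(n_chains=1)

    def test_wishart_df_floor(self):
        with pytest.raises(ValueError):
            PriorSettings(wishart_df=1.0).resolve(m=3)


@pytest.fixture(scope="module")
def small_fit(small_dataset):
    data, truth = small_dataset
    model = LatentClassCFA(data)
    with pytest.warns(UserWarning):
        res = model.fit(chains=2, iterations=800, burnin=400, seed=5)
    return data, truth, model, res


class TestLatentClassFit:
    def test_posterior_shapes_and_ranges(self, small_fit):
        data, truth, model, res = small_fit
        assert res.bot_probability.shape == (data.n_persons,)
        assert np.all((res.bot_probability >= 0) & (res.bot_probability <= 1))
        assert res.draws["beta"].shape == (2, 400, 3)
        assert set(res.classify()) <= {"human", "bot"}
        assert (res.rhat.index == res.ess.index).all()

    def test_class2_has_no_factor_structure(self, small_fit):
        """The bot class is intercept-only: no loadings are drawn for it."""
        _, _, _, res = small_fit
        assert "lam2" not in res.draws
        assert {"tau2", "sigma2"} <= set(res.draws)

    def test_seed_determinism(self, small_dataset):
        data, _ = small_dataset
        kwargs = dict(chains=2, iterations=400, burnin=200, seed=42)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = LatentClassCFA(data).fit(**kwargs)
            r2 = LatentClassCFA(data).fit(**kwargs)
        assert np.array_equal(r1.draws["lam"], r2.draws["lam"])
        assert np.array_equal(r1.bot_probability, r2.bot_probability)

    def test_summary_frame(self, small_fit):
        _, _, _, res = small_fit
        s = res.summary()
        assert {"mean", "sd", "2.5%", "97.5%", "rhat", "ess"} <= set(s.columns)
        assert "beta[2]" in s.index
        # scaling loadings are fixed constants, not monitored
        assert "lam[0]" not in s.index

    def test_bots_receive_higher_posterior_probability(self, small_fit):
        """Even at short chains the mixture assigns true bots systematically
        higher posterior bot probabilities than true humans."""
        _, truth, _, res = small_fit
        assert (res.bot_probability[truth.class_labels == "bot"].mean()
                > res.bot_probability[truth.class_labels == "human"].mean() + 0.5)

    def test_from_dataframe_roundtrip(self, small_dataset):
        data, _ = small_dataset
        df = data.to_dataframe()
        factors = {f"F{k + 1}": [n for n, f in zip(data.item_names,
                                                   data.item_factor_map) if f == k]
                   for k in range(3)}
        model = LatentClassCFA.from_dataframe(df, factors)
        assert np.array_equal(model.data.responses, data.responses)


class TestBinaryFamily:
    def test_smoke_fit_recovers_contamination_direction(self, rng):
        n, p = 200, 8
        fmap = np.repeat([0, 1], 4)
        eta = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], n)
        mu = 0.3 + 1.0 * eta[:, fmap]
        y = (rng.random((n, p)) < expit(mu)).astype(int)
        bots = np.zeros(n, dtype=bool)
        bots[:50] = True
        y[bots] = rng.integers(0, 2, (50, p))
        data = SurveyDataset(responses=y, item_factor_map=fmap, family="binary",
                             category_range=(0, 1))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = LatentClassCFA(data).fit(chains=2, iterations=600,
                                           burnin=300, seed=8)
        assert res.bot_probability.shape == (n,)
        assert "sigma1" not in res.draws  # no dispersion for Bernoulli items
        # flagged respondents should be disproportionately the true bots
        assert (res.bot_probability[bots].mean()
                > res.bot_probability[~bots].mean())
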
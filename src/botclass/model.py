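"""Two-class mixture CFA for bot detection, and the one-class Bayesian CFA.

The mixture has class 1 following a confirmatory factor model and class 2 an
intercept-only model of content-independent responding; class membership is
predicted from two person-level indices through a logistic model,

    P(C_i = 1 | y1_i, y2_i) = expit(b0 + b1 * y1_i + b2 * y2_i).

Because class 2 has no loadings, the classes cannot label-switch through a
parameter permutation; the "bot" class is structurally the one whose
likelihood never references the factor scores.

Usage follows the Model / Results convention::

    model = LatentClassCFA(dataset)            # indices computed automatically
    res = model.fit(chains=3, iterations=12_000, burnin=6_000, seed=1)
    res.summary()
    res.classify(threshold=0.5)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from . import _gibbs
from .datasets import SurveyDataset
from .diagnostics import effective_sample_size, split_rhat
from .personfit import PersonIndices, compute_person_indices, fit_ml_cfa

__all__ = [
    "ModelSpec",
    "PriorSettings",
    "McmcSettings",
    "LatentClassCFA",
    "BayesianCFA",
    "LcCfaResults",
    "CfaResults",
    "class_probability",
    "classify_persons",
    "mixture_loglik_person",
    "standardized_loadings",
]

RHAT_CUTOFF = 1.01


@dataclass(frozen=True)
class ModelSpec:
    """Measurement specification: factor map, response family, class predictors."""

    item_factor_map: np.ndarray
    family: str = "continuous"
    n_classes: int = 2
    predictors: tuple[str, ...] = ("y1", "y2")
    fix_class2_intercepts: bool = False

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("the latent-class CFA is a two-class model")
        fmap = np.asarray(self.item_factor_map, dtype=np.int64)
        object.__setattr__(self, "item_factor_map", fmap)
        m = fmap.max() + 1
        if set(fmap.tolist()) != set(range(m)):
            raise ValueError("factor indices must be consecutive from 0")

    @property
    def n_factors(self) -> int:
        return int(self.item_factor_map.max()) + 1

    @property
    def scaling_items(self) -> np.ndarray:
        """First mapped item per factor; its loading is fixed to 1."""
        return np.array([np.flatnonzero(self.item_factor_map == k)[0]
                         for k in range(self.n_factors)])

    @property
    def free_items(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.item_factor_map.size), self.scaling_items)


@dataclass(frozen=True)
class PriorSettings:
    """Weakly informative defaults on the scale of standardized indices."""

    tau_mean: float = 0.0
    tau_var: float = 1.0
    loading_var: float = 1.0        # N(0,1) truncated to [0, inf) on free loadings
    wishart_scale: np.ndarray | None = None   # rate matrix; identity if None
    wishart_df: float | None = None           # m if None
    beta_mean: float = 0.0
    beta_var: float = 10.0
    sigma_shape: float = 9.0
    sigma_rate: float = 4.0

    def resolve(self, m: int) -> "PriorSettings":
        scale = np.eye(m) if self.wishart_scale is None else np.asarray(self.wishart_scale)
        df = float(m) if self.wishart_df is None else float(self.wishart_df)
        if df < m:
            raise ValueError("Wishart degrees of freedom must be >= the number of factors")
        if self.sigma_shape <= 0 or self.sigma_rate <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        return PriorSettings(
            tau_mean=self.tau_mean, tau_var=self.tau_var,
            loading_var=self.loading_var, wishart_scale=scale, wishart_df=df,
            beta_mean=self.beta_mean, beta_var=self.beta_var,
            sigma_shape=self.sigma_shape, sigma_rate=self.sigma_rate,
        )


@dataclass(frozen=True)
class McmcSettings:
    """Chain configuration; defaults follow the reference analysis."""

    n_chains: int = 3
    n_iter: int = 12_000
    n_burnin: int = 6_000
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("burn-in must be shorter than the total chain")
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required for split-Rhat")


# --------------------------------------------------------------- functions

def class_probability(y1_i: float, y2_i: float, beta) -> float:
    """P(C_i = 1 | indices): expit of the linear predictor."""
    beta = np.asarray(beta, dtype=float)
    return float(expit(beta[0] + beta[1] * y1_i + beta[2] * y2_i))


def mixture_loglik_person(y_i, theta: dict, pi_i: float, spec: ModelSpec,
                          gh_points: int = 21) -> float:
    """Log mixture density of one response vector.

    ``log[pi * f1(y|theta) + (1-pi) * f2(y|theta)]``.  For continuous items the
    class-1 factor scores integrate analytically into a multivariate normal
    marginal; for binary/count items they are integrated by tensor-product
    Gauss-Hermite quadrature.
    """
    y = np.asarray(y_i, dtype=float)
    fmap = spec.item_factor_map
    lam = np.asarray(theta["lam"], dtype=float)
    tau1 = np.asarray(theta["tau1"], dtype=float)
    tau2 = np.asarray(theta["tau2"], dtype=float)
    phi = np.asarray(theta["phi"], dtype=float)
    m = spec.n_factors

    if spec.family == "continuous":
        sigma1 = np.asarray(theta["sigma1"], dtype=float)
        sigma2 = np.asarray(theta["sigma2"], dtype=float)
        cov1 = lam[:, None] * lam[None, :] * phi[np.ix_(fmap, fmap)]
        cov1 = cov1 + np.diag(sigma1)
        if np.linalg.eigvalsh(cov1).min() <= 0:
            raise ValueError(f"class-1 implied covariance not PD; theta={theta}")
        logf1 = float(_gibbs._mvn_logpdf_rows(y[None, :], tau1, cov1)[0])
        logf2 = float(_gibbs._indep_normal_logpdf_rows(y[None, :], tau2, sigma2)[0])
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(gh_points)
        grids = np.meshgrid(*([nodes] * m), indexing="ij")
        z = np.column_stack([g.ravel() for g in grids])          # standard normal nodes
        wgrid = np.meshgrid(*([weights] * m), indexing="ij")
        logw = np.sum(np.log([w.ravel() for w in wgrid]), axis=0) - 0.5 * m * np.log(2 * np.pi)
        L = np.linalg.cholesky(phi)
        eta = z @ L.T
        mu = tau1 + lam * eta[:, fmap]
        ll_nodes = _gibbs._ll_matrix(y[None, :], mu, spec.family).sum(axis=1)
        logf1 = float(logsumexp(ll_nodes + logw))
        logf2 = float(_gibbs._ll_matrix(y[None, :], tau2, spec.family).sum())

    if pi_i <= 0.0:
        return logf2
    if pi_i >= 1.0:
        return logf1
    return float(np.logaddexp(np.log(pi_i) + logf1, np.log1p(-pi_i) + logf2))


def standardized_loadings(lam_draws, phi_draws, sigma_draws, fmap) -> np.ndarray:
    """Per-draw standardized loadings ``lam sqrt(phi_kk) / sqrt(lam^2 phi_kk + sigma^2)``.

    Accepts draw arrays with any leading shape; the trailing axes are
    (item,) for loadings/residuals and (item-factor tril or matrix) for phi.
    """
    lam = np.asarray(lam_draws, dtype=float)
    sigma = np.asarray(sigma_draws, dtype=float)
    phi_kk = np.asarray(phi_draws, dtype=float)[..., fmap]
    implied = lam ** 2 * phi_kk + sigma
    if np.any(implied <= 0):
        raise ValueError("nonpositive implied item variance in standardized loadings")
    return lam * np.sqrt(phi_kk) / np.sqrt(implied)


def classify_persons(post: "LcCfaResults", threshold: float = 0.5) -> np.ndarray:
    """Label each respondent: bot iff posterior bot probability > threshold.

    Ties at exactly the threshold are kept as human (conservative).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("classification threshold must lie strictly inside (0, 1)")
    return np.where(post.bot_probability > threshold, "bot", "human")


# ----------------------------------------------------------------- results

def _tril_names(m: int) -> list[str]:
    i, j = np.tril_indices(m)
    return [f"phi[{a},{b}]" for a, b in zip(i, j)]


class _BaseResults:
    """Shared posterior container: draws, diagnostics, summaries."""

    _PARAM_ORDER = ("tau1", "lam", "sigma1", "tau2", "sigma2", "phi", "beta")

    def __init__(self, draws: dict[str, np.ndarray], spec: ModelSpec,
                 settings: McmcSettings):
        self.draws = draws    # name -> (chains, kept, dim)
        self.spec = spec
        self.settings = settings
        self._flat = self._flatten()
        self.rhat = pd.Series({k: split_rhat(v) for k, v in self._flat.items()})
        self.ess = pd.Series({k: effective_sample_size(v) for k, v in self._flat.items()})
        self.converged = bool((self.rhat < RHAT_CUTOFF).all())
        if not self.converged:
            bad = self.rhat[self.rhat >= RHAT_CUTOFF]
            warnings.warn(
                f"{len(bad)} parameter(s) with split-Rhat >= {RHAT_CUTOFF}; "
                f"worst: {bad.idxmax()} = {bad.max():.4f}", stacklevel=3)

    def _flatten(self) -> dict[str, np.ndarray]:
        m = self.spec.n_factors
        names: dict[str, list[str]] = {}
        p = self.spec.item_factor_map.size
        names["tau1"] = [f"tau1[{j}]" for j in range(p)]
        names["tau2"] = [f"tau2[{j}]" for j in range(p)]
        names["sigma1"] = [f"sigma1[{j}]" for j in range(p)]
        names["sigma2"] = [f"sigma2[{j}]" for j in range(p)]
        names["lam"] = [f"lam[{j}]" for j in range(p)]
        names["phi"] = _tril_names(m)
        names["beta"] = [f"beta[{r}]" for r in range(3)]
        flat = {}
        free = set(self.spec.free_items.tolist())
        # with (near-)zero class-2 occupancy the skip-when-empty kernel never
        # explores tau2/sigma2, so their Rhat is meaningless; exclude them
        skip = set()
        if getattr(self, "class2_occupancy", 1.0) < 0.01:
            skip = {"tau2", "sigma2"}
        for par in self._PARAM_ORDER:
            if par not in self.draws or par in skip:
                continue
            arr = self.draws[par]
            for d in range(arr.shape[-1]):
                if par == "lam" and d not in free:
                    continue  # fixed scaling loadings are constants
                flat[names[par][d]] = arr[..., d]
        return flat

    @property
    def posterior_means(self) -> pd.Series:
        return pd.Series({k: float(v.mean()) for k, v in self._flat.items()})

    def summary(self) -> pd.DataFrame:
        """Posterior summary: mean, SD, central 95% interval, Rhat, ESS."""
        rows = {}
        for name, v in self._flat.items():
            flat = v.reshape(-1)
            rows[name] = {
                "mean": flat.mean(), "sd": flat.std(ddof=1),
                "2.5%": np.quantile(flat, 0.025), "97.5%": np.quantile(flat, 0.975),
                "rhat": self.rhat[name], "ess": self.ess[name],
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def standardized_loadings_draws(self) -> np.ndarray:
        """Standardized class-1 loadings per draw, shape (chains, kept, items)."""
        if self.spec.family != "continuous":
            raise NotImplementedError(
                "standardized loadings are defined for the continuous family")
        m = self.spec.n_factors
        diag_pos = np.array([np.flatnonzero(
            (np.tril_indices(m)[0] == k) & (np.tril_indices(m)[1] == k))[0]
            for k in range(m)])
        phi_kk = self.draws["phi"][..., diag_pos]
        return standardized_loadings(self.draws["lam"], phi_kk,
                                     self.draws["sigma1"], self.spec.item_factor_map)

    @property
    def standardized_loadings_mean(self) -> np.ndarray:
        d = self.standardized_loadings_draws()
        return d.reshape(-1, d.shape[-1]).mean(axis=0)

    def factor_correlations_mean(self) -> np.ndarray:
        """Posterior-mean factor correlation matrix (per-draw normalized)."""
        m = self.spec.n_factors
        i, j = np.tril_indices(m)
        phi = self.draws["phi"]
        full = np.zeros(phi.shape[:-1] + (m, m))
        full[..., i, j] = phi
        full[..., j, i] = phi
        d = np.sqrt(np.einsum("...kk->...k", full))
        corr = full / (d[..., :, None] * d[..., None, :])
        return corr.reshape(-1, m, m).mean(axis=0)

    def factor_variances_mean(self) -> np.ndarray:
        m = self.spec.n_factors
        i, j = np.tril_indices(m)
        diag_pos = np.flatnonzero(i == j)
        return self.draws["phi"][..., diag_pos].reshape(-1, m).mean(axis=0)

    def plot_trace(self, names=None, ax=None):
        """Quick trace plot of selected (default: class-model) parameters."""
        import matplotlib.pyplot as plt

        names = list(names or [n for n in self._flat if n.startswith("beta")])
        fig, axes = plt.subplots(len(names), 1, figsize=(7, 1.8 * len(names)),
                                 squeeze=False)
        for axis, name in zip(axes[:, 0], names):
            for c in range(self._flat[name].shape[0]):
                axis.plot(self._flat[name][c], lw=0.5)
            axis.set_ylabel(name)
        fig.tight_layout()
        return fig


class CfaResults(_BaseResults):
    """Posterior of the one-class Bayesian CFA baseline."""


class LcCfaResults(_BaseResults):
    """Posterior of the latent-class CFA, with per-person bot probabilities."""

    def __init__(self, draws, spec, settings, bot_probability, indices,
                 class2_occupancy: float = 1.0):
        self.bot_probability = np.asarray(bot_probability)
        self.indices = indices
        #: fraction of kept sweeps in which at least one person sat in class 2
        self.class2_occupancy = class2_occupancy
        super().__init__(draws, spec, settings)

    def classify(self, threshold: float = 0.5) -> np.ndarray:
        return classify_persons(self, threshold)

    @property
    def beta_draws(self) -> np.ndarray:
        return self.draws["beta"]

    def beta_credible_interval(self, prob: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - prob) / 2, 1 - (1 - prob) / 2
        flat = self.draws["beta"].reshape(-1, 3)
        return pd.DataFrame(
            {"lower": np.quantile(flat, lo, axis=0),
             "upper": np.quantile(flat, hi, axis=0)},
            index=["beta[0]", "beta[1]", "beta[2]"],
        )

    def classification_frame(self, threshold: float = 0.5,
                             person_ids=None) -> pd.DataFrame:
        ids = person_ids if person_ids is not None else np.arange(
            self.bot_probability.size)
        return pd.DataFrame({
            "person_id": ids,
            "p_bot": self.bot_probability,
            "class": self.classify(threshold),
        })


# ------------------------------------------------------------------ models

class _BaseModel:
    def __init__(self, data: SurveyDataset, spec: ModelSpec | None = None,
                 priors: PriorSettings | None = None):
        self.data = data
        self.spec = spec or ModelSpec(item_factor_map=data.item_factor_map,
                                      family=data.family)
        self.priors = (priors or PriorSettings()).resolve(self.spec.n_factors)
        if data.responses.shape[1] != self.spec.item_factor_map.size:
            raise ValueError("factor map length does not match the item count")
        self._ml_fit = None
        self._base_init: dict | None = None

    def _beta_init(self) -> np.ndarray:
        return np.array([np.log(0.9 / 0.1), 0.0, 0.0])

    def _initial_values(self, rng: np.random.Generator) -> dict:
        """Start class-1 parameters at the preliminary ML-CFA solution."""
        if self._base_init is not None:
            init = {k: v.copy() for k, v in self._base_init.items()}
            init["tau1"] = init["tau1"] + 0.05 * rng.standard_normal(init["tau1"].size)
            init["beta"] = init["beta"] + 0.1 * rng.standard_normal(3)
            return init
        y = self.data.responses.astype(float)
        p = y.shape[1]
        m = self.spec.n_factors
        # class 2 starts at its hypothesized meaning -- uniform random
        # responding over the observed code range -- so that it attracts
        # genuinely content-independent rows rather than noisy humans
        lo, hi = (self.data.category_range
                  if self.data.category_range is not None
                  else (y.min(), y.max()))
        n_codes = hi - lo + 1
        init = {
            "tau2": np.full(p, (lo + hi) / 2.0),
            "sigma2": np.full(p, max((n_codes ** 2 - 1) / 12.0, 0.25)),
            "beta": self._beta_init(),
        }
        if self.spec.family == "continuous":
            if self._ml_fit is None:
                self._ml_fit = fit_ml_cfa(self.data)
            fit = self._ml_fit
            lam = np.zeros(p)
            lam[self.spec.free_items] = np.maximum(
                fit.loadings[self.spec.free_items,
                             self.spec.item_factor_map[self.spec.free_items]], 0.01)
            lam[self.spec.scaling_items] = 1.0
            init.update(tau1=fit.sample_mean.copy(), lam=lam,
                        sigma1=np.maximum(fit.residual_variances, 1e-3),
                        phi=fit.factor_cov + 1e-6 * np.eye(m))
        else:
            if self.spec.family == "binary":
                pbar = np.clip(y.mean(axis=0), 0.01, 0.99)
                tau = np.log(pbar / (1 - pbar))
            else:
                tau = np.log(np.maximum(y.mean(axis=0), 0.1))
            init.update(tau1=tau.copy(), tau2=tau.copy(), lam=np.ones(p),
                        phi=np.eye(m))
        self._base_init = {k: np.asarray(v, dtype=float).copy()
                           for k, v in init.items()}
        return self._initial_values(rng)

    def _run(self, mixture: bool, X, settings: McmcSettings,
             progress: bool = False):
        seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
        chains = []
        for c in range(settings.n_chains):
            rng = np.random.default_rng(seeds[c])
            init = self._initial_values(rng)
            if self.spec.family == "continuous":
                res = _gibbs.run_continuous_chain(
                    self.data.responses.astype(float), X,
                    self.spec.item_factor_map, self.spec.free_items,
                    self.priors, settings.n_iter, settings.n_burnin, rng, init,
                    mixture=mixture, thin=settings.thin)
            else:
                res = _gibbs.run_glm_chain(
                    self.data.responses.astype(float), X,
                    self.spec.item_factor_map, self.spec.free_items,
                    self.priors, settings.n_iter, settings.n_burnin, rng, init,
                    family=self.spec.family, mixture=mixture, thin=settings.thin,
                    fix_class2_intercepts=self.spec.fix_class2_intercepts)
            chains.append(res)
        draws = {k: np.stack([c[k] for c in chains])
                 for k in chains[0] if k not in ("pbot", "occupancy")}
        pbot = np.mean([c["pbot"] for c in chains], axis=0)
        occupancy = float(np.mean([c.get("occupancy", 0.0) for c in chains]))
        return draws, pbot, occupancy

    @staticmethod
    def _settings(chains, iterations, burnin, seed, thin, settings):
        if settings is not None:
            return settings
        return McmcSettings(n_chains=chains, n_iter=iterations,
                            n_burnin=burnin, seed=seed, thin=thin)


class LatentClassCFA(_BaseModel):
    """Two-class mixture CFA with person-index class predictors.

    Parameters
    ----------
    data : SurveyDataset
    indices : PersonIndices, optional
        Person-fit and variability indices; computed from the data (via a
        preliminary ML CFA) and z-scored when not supplied.
    spec, priors : optional overrides of the measurement spec and priors.
    """

    def __init__(self, data, indices: PersonIndices | None = None,
                 spec=None, priors=None, standardize_indices: bool = True):
        super().__init__(data, spec, priors)
        if indices is None:
            if self.spec.family == "continuous":
                self._ml_fit = fit_ml_cfa(data)
            indices = compute_person_indices(data, fit=self._ml_fit,
                                             standardize=standardize_indices)
        if indices.y1.size != data.n_persons:
            raise ValueError("indices were not computed on this dataset")
        self.indices = indices

    def _beta_init(self) -> np.ndarray:
        """Start the class model in the basin matching the intended class
        meaning.  Uniform random responding has a known variability:
        E[y2] = (K^2 - 1)/12 for K equally likely codes.  If some respondents'
        raw variability index is consistent with that value (above the midpoint
        between the sample median and the uniform expectation), the coefficient
        on the variability index starts negative so those rows seed class 2;
        otherwise it starts at zero and the chains begin with everyone in
        class 1, avoiding a spurious "noisy humans" class on clean data."""
        from .personfit import variability_y2

        y = self.data.responses.astype(float)
        lo, hi = (self.data.category_range
                  if self.data.category_range is not None
                  else (y.min(), y.max()))
        uniform_var = max(((hi - lo + 1) ** 2 - 1) / 12.0, 1e-6)
        y2_raw = variability_y2(self.data)
        cut = 0.5 * (float(np.median(y2_raw)) + uniform_var)
        frac_uniform_like = float(np.mean(y2_raw > cut))
        sd = float(np.std(self.indices.y2)) or 1.0
        slope = -3.0 / sd if frac_uniform_like >= 0.02 else 0.0
        return np.array([np.log(0.9 / 0.1), 0.0, slope])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors: dict[str, list[str]],
                       family: str = "continuous", **kwargs) -> "LatentClassCFA":
        items = [it for cols in factors.values() for it in cols]
        fmap = np.concatenate([np.full(len(cols), k)
                               for k, cols in enumerate(factors.values())])
        data = SurveyDataset(responses=df[items].to_numpy(), item_factor_map=fmap,
                             family=family, item_names=items)
        return cls(data, **kwargs)

    def fit(self, chains: int = 3, iterations: int = 12_000, burnin: int = 6_000,
            seed: int = 0, thin: int = 1, settings: McmcSettings | None = None,
            progress: bool = False) -> LcCfaResults:
        settings = self._settings(chains, iterations, burnin, seed, thin, settings)
        X = np.column_stack([np.ones(self.data.n_persons),
                             self.indices.y1, self.indices.y2])
        draws, pbot, occupancy = self._run(True, X, settings, progress)
        return LcCfaResults(draws, self.spec, settings, pbot, self.indices,
                            class2_occupancy=occupancy)


class BayesianCFA(_BaseModel):
    """One-class Bayesian CFA: the class-1 measurement model without mixture.

    Identical priors to the latent-class model for all shared parameters;
    serves as the naive baseline that ignores contamination.
    """

    @classmethod
    def from_dataframe(cls, df, factors, family="continuous", **kwargs):
        items = [it for cols in factors.values() for it in cols]
        fmap = np.concatenate([np.full(len(cols), k)
                               for k, cols in enumerate(factors.values())])
        data = SurveyDataset(responses=df[items].to_numpy(), item_factor_map=fmap,
                             family=family, item_names=items)
        return cls(data, **kwargs)

    def fit(self, chains: int = 3, iterations: int = 12_000, burnin: int = 6_000,
            seed: int = 0, thin: int = 1, settings: McmcSettings | None = None,
            progress: bool = False) -> CfaResults:
        settings = self._settings(chains, iterations, burnin, seed, thin, settings)
        draws, _, _ = self._run(False, None, settings, progress)
        draws = {k: v for k, v in draws.items() if k not in ("tau2", "sigma2", "beta")}
        return CfaResults(draws, self.spec, settings)
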
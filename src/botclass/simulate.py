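"""Synthetic questionnaire data with a known bot subpopulation.

Humans answer according to a standardized simple-structure factor model whose
continuous latent responses are cut into Likert categories at fixed thresholds;
bots pick every category uniformly at random.  The generator keeps full ground
truth (loadings, factor covariance, class labels) so that classification
accuracy and parameter bias can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .datasets import SurveyDataset

__all__ = [
    "SimulationDesign",
    "TrueParameters",
    "sample_design_factors",
    "build_true_parameters",
    "generate_human_responses",
    "generate_bot_responses",
    "generate_dataset",
    "observed_metric_attenuation",
]

#: communalities are clipped to this open interval so residual variances stay positive
_COMMUNALITY_CLIP = (0.05, 0.95)


@dataclass(frozen=True)
class SimulationDesign:
    """One cell of the simulation design.

    Defaults reproduce the reference study conditions: six 6-point Likert items
    per factor, thresholds at (-2,-1,0,1,2) on the standard-normal latent
    response, average item communality drawn uniformly from [0.25, 0.64]
    (individual items within +/-0.15 of the average), and a single factor
    intercorrelation drawn uniformly from [0, 0.7].
    """

    n_persons: int = 400
    n_factors: int = 3
    items_per_factor: int = 6
    prop_bots: float = 0.25
    communality_mean_range: tuple[float, float] = (0.25, 0.64)
    communality_halfwidth: float = 0.15
    rho_range: tuple[float, float] = (0.0, 0.7)
    n_categories: int = 6
    thresholds: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons < 1 or self.n_factors < 1 or self.items_per_factor < 1:
            raise ValueError("n_persons, n_factors and items_per_factor must be positive")
        if not 0.0 <= self.prop_bots <= 1.0:
            raise ValueError("prop_bots must lie in [0, 1]")
        if self.n_categories < 2:
            raise ValueError("need at least two response categories")
        thr = np.asarray(self.thresholds, dtype=float)
        if thr.size != self.n_categories - 1 or np.any(np.diff(thr) <= 0):
            raise ValueError("thresholds must be strictly increasing with length n_categories-1")
        for lo, hi in (self.communality_mean_range, self.rho_range):
            if lo > hi:
                raise ValueError("interval bounds must be ordered")
        lo, hi = self.communality_mean_range
        if not (0.0 < lo and hi < 1.0):
            raise ValueError("communality_mean_range must lie inside (0, 1)")
        if self.communality_halfwidth < 0:
            raise ValueError("communality_halfwidth must be nonnegative")

    @property
    def n_items(self) -> int:
        return self.n_factors * self.items_per_factor


@dataclass
class TrueParameters:
    """Generating values retained for recovery and bias scoring.

    ``loadings_std_observed`` are the population standardized loadings of the
    *categorized* items: cutting a standard-normal response into ``K``
    categories shrinks every inter-item correlation by a constant factor, so
    the loadings any estimator of the observed responses can recover are
    ``attenuation * loadings_std``.  Factor correlations are unaffected.
    """

    loading_matrix: np.ndarray          # p x m, simple structure
    factor_cov: np.ndarray              # m x m, unit diagonal
    residual_variances: np.ndarray      # length p
    intercepts: np.ndarray              # length p, zeros
    class_labels: np.ndarray            # length N over {"human", "bot"}
    communality_mean: float
    rho: float
    item_factor_map: np.ndarray = field(default=None)  # length p, factor index per item
    attenuation: float = 1.0

    @property
    def loadings_std(self) -> np.ndarray:
        """Generating standardized loading per item (sqrt of its communality)."""
        return self.loading_matrix[np.arange(self.loading_matrix.shape[0]),
                                   self.item_factor_map]

    @property
    def loadings_std_observed(self) -> np.ndarray:
        return self.attenuation * self.loadings_std

    @property
    def n_bots(self) -> int:
        return int(np.sum(self.class_labels == "bot"))


def observed_metric_attenuation(thresholds, n_categories: int) -> float:
    """Attenuation of standardized loadings caused by categorization.

    For ``Y = k`` iff ``d_{k-1} <= Y* < d_k`` with ``Y*`` standard normal, the
    first Hermite coefficient of the step function is ``a1 = sum_k phi(d_k)``
    and ``Corr(Y_a, Y_b) ~= a1^2 r / Var(Y)`` for latent correlation ``r``
    (higher-order terms are below 1e-3 for 6 equidistant categories).  The
    population standardized loading of a categorized item is therefore
    ``a1 / sd(Y)`` times the latent one.
    """
    thr = np.asarray(thresholds, dtype=float)
    a1 = norm.pdf(thr).sum()
    edges = np.concatenate(([-np.inf], thr, [np.inf]))
    probs = np.diff(norm.cdf(edges))
    cats = np.arange(1, n_categories + 1, dtype=float)
    mean = probs @ cats
    var = probs @ (cats - mean) ** 2
    return float(a1 / np.sqrt(var))


def sample_design_factors(design: SimulationDesign, rng: np.random.Generator):
    """Draw the replication-level random design factors.

    Returns ``(communality_mean, rho)`` sampled uniformly from the design
    ranges; a degenerate interval returns its constant.
    """
    lo, hi = design.communality_mean_range
    communality_mean = lo if lo == hi else rng.uniform(lo, hi)
    lo, hi = design.rho_range
    rho = lo if lo == hi else rng.uniform(lo, hi)
    return float(communality_mean), float(rho)


def build_true_parameters(
    design: SimulationDesign,
    communality_mean: float,
    rho: float,
    rng: np.random.Generator,
) -> TrueParameters:
    """Draw item communalities and assemble the generating model.

    Item communalities are uniform on ``communality_mean +/- halfwidth``
    (clipped away from 0 and 1), loadings are their positive square roots,
    residual variances complete each item to unit variance, and the factor
    covariance is an equicorrelation matrix with unit diagonal.
    """
    p, m = design.n_items, design.n_factors
    lo = communality_mean - design.communality_halfwidth
    hi = communality_mean + design.communality_halfwidth
    h2 = rng.uniform(lo, hi, size=p) if lo != hi else np.full(p, lo)
    h2 = np.clip(h2, *_COMMUNALITY_CLIP)

    fmap = np.repeat(np.arange(m), design.items_per_factor)
    loading_matrix = np.zeros((p, m))
    loading_matrix[np.arange(p), fmap] = np.sqrt(h2)

    factor_cov = np.full((m, m), rho)
    np.fill_diagonal(factor_cov, 1.0)
    if m > 1 and np.linalg.eigvalsh(factor_cov).min() <= 1e-12:
        raise ValueError("factor covariance matrix is not positive definite")

    return TrueParameters(
        loading_matrix=loading_matrix,
        factor_cov=factor_cov,
        residual_variances=1.0 - h2,
        intercepts=np.zeros(p),
        class_labels=np.array([]),
        communality_mean=float(communality_mean),
        rho=float(rho),
        item_factor_map=fmap,
        attenuation=observed_metric_attenuation(design.thresholds, design.n_categories),
    )


def generate_human_responses(
    params: TrueParameters,
    n: int,
    thresholds,
    rng: np.random.Generator,
) -> np.ndarray:
    """Thresholded-normal Likert responses for ``n`` attentive respondents.

    Latent responses are ``Y* = tau + Lambda eta + eps`` with
    ``eta ~ MVN(0, Phi)`` and independent normal residuals; ``Y* `` is mapped
    to category ``k`` when ``d_{k-1} <= Y* < d_k``, coded ``1..K``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p, m = params.loading_matrix.shape
    eta = rng.multivariate_normal(np.zeros(m), params.factor_cov, size=n,
                                  method="cholesky")
    eps = rng.standard_normal((n, p)) * np.sqrt(params.residual_variances)
    ystar = params.intercepts + eta @ params.loading_matrix.T + eps
    thr = np.asarray(thresholds, dtype=float)
    return (np.searchsorted(thr, ystar, side="right") + 1).astype(np.int64)


def generate_bot_responses(n: int, p: int, n_categories: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Uniform categorical responses: every cell i.i.d. on ``{1..K}``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return rng.integers(1, n_categories + 1, size=(n, p), dtype=np.int64)


def generate_dataset(design: SimulationDesign) -> tuple[SurveyDataset, TrueParameters]:
    """Generate one replication: responses, shuffled, with aligned ground truth.

    Exactly ``round(prop_bots * N)`` rows are bots; rows are shuffled so class
    membership is not encoded in row order.  Fully reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    communality_mean, rho = sample_design_factors(design, rng)
    params = build_true_parameters(design, communality_mean, rho, rng)

    n = design.n_persons
    n_bots = int(round(design.prop_bots * n))
    if n_bots == 0 and design.prop_bots > 0:
        warnings.warn("prop_bots > 0 but the rounded bot count is zero", stacklevel=2)
    n_humans = n - n_bots

    blocks, labels = [], []
    if n_humans:
        blocks.append(generate_human_responses(params, n_humans, design.thresholds, rng))
        labels.append(np.full(n_humans, "human"))
    if n_bots:
        blocks.append(generate_bot_responses(n_bots, design.n_items, design.n_categories, rng))
        labels.append(np.full(n_bots, "bot"))
    responses = np.vstack(blocks)
    class_labels = np.concatenate(labels)

    order = rng.permutation(n)
    responses = responses[order]
    params.class_labels = class_labels[order]

    item_names = [f"F{k + 1}_I{j + 1}" for k in range(design.n_factors)
                  for j in range(design.items_per_factor)]
    dataset = SurveyDataset(
        responses=responses,
        item_factor_map=params.item_factor_map.copy(),
        family="continuous",
        category_range=(1, design.n_categories),
        item_names=item_names,
    )
    return dataset, params
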
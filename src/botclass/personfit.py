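"""Person-level predictors of random responding.

Two indices feed the latent-class model:

* ``y1`` — a likelihood-based person-fit index: minus twice the gap between a
  respondent's multivariate-normal log-likelihood under the model-implied
  moments of a preliminary ML confirmatory factor analysis and under the
  saturated sample moments.
* ``y2`` — a nonparametric variability index: the respondent's sample variance
  across the items of each factor, averaged over factors.  Content-driven
  responses within a factor are similar, so humans score low and uniform
  random responders high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .datasets import SurveyDataset

__all__ = [
    "CfaMlFit",
    "PersonIndices",
    "fit_ml_cfa",
    "individual_loglik",
    "person_fit_y1",
    "variability_y2",
    "compute_person_indices",
    "standardize_indices",
]

_RIDGE = 1e-8
_MAX_ITER = 500
_TOL = 1e-6


@dataclass
class CfaMlFit:
    """Maximum-likelihood CFA estimates plus implied and sample moments."""

    loadings: np.ndarray            # p x m
    factor_cov: np.ndarray          # m x m
    residual_variances: np.ndarray  # length p
    implied_mean: np.ndarray        # mu (saturated: the sample mean)
    implied_cov: np.ndarray         # Sigma = Lambda Phi Lambda' + diag(sigma2)
    sample_mean: np.ndarray
    sample_cov: np.ndarray
    converged: bool
    loglik: float


@dataclass
class PersonIndices:
    """Per-respondent (y1, y2) pairs, optionally z-scored across respondents."""

    y1: np.ndarray
    y2: np.ndarray
    standardized: bool = False
    standardization_constants: dict | None = None

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.y1, self.y2])


def _implied_cov(lam_free, log_sigma2, phi_chol_param, fmap, p, m):
    """Rebuild Lambda, Phi, sigma2 and the implied covariance from the packed vector."""
    lam = np.zeros((p, m))
    scaling = _scaling_items(fmap, m)
    lam[scaling, fmap[scaling]] = 1.0
    free = np.setdiff1d(np.arange(p), scaling)
    lam[free, fmap[free]] = lam_free
    L = np.zeros((m, m))
    idx = np.tril_indices(m)
    L[idx] = phi_chol_param
    L[np.diag_indices(m)] = np.exp(np.diag(L))
    phi = L @ L.T
    sigma2 = np.exp(log_sigma2)
    return lam, phi, sigma2, lam @ phi @ lam.T + np.diag(sigma2)


def _scaling_items(fmap: np.ndarray, m: int) -> np.ndarray:
    """First mapped item of each factor (its loading is fixed to 1)."""
    return np.array([np.flatnonzero(fmap == k)[0] for k in range(m)])


def fit_ml_cfa(data: SurveyDataset) -> CfaMlFit:
    """Fit a simple-structure CFA by Gaussian maximum likelihood.

    The mean model is saturated (implied mean = sample mean); the covariance
    structure ``Lambda Phi Lambda' + diag(sigma2)`` is maximized by L-BFGS with
    the first loading per factor fixed to 1.  Integer Likert codes are treated
    as continuous.  On non-convergence the starting values are returned with
    ``converged=False`` (the person-fit index remains computable); a
    near-singular sample covariance receives a small ridge.
    """
    y = data.responses.astype(float)
    n, p = y.shape
    fmap = data.item_factor_map
    m = data.n_factors
    ybar = y.mean(axis=0)
    S = np.cov(y, rowvar=False, ddof=1)
    if np.linalg.eigvalsh(S).min() < 1e-10:
        warnings.warn("sample covariance near-singular; adding a small ridge",
                      stacklevel=2)
        S = S + _RIDGE * np.mean(np.diag(S)) * np.eye(p)

    scaling = _scaling_items(fmap, m)
    n_free = p - m

    def unpack(theta):
        return (theta[:n_free], theta[n_free:n_free + p], theta[n_free + p:])

    def objective(theta):
        _, _, _, sigma = _implied_cov(*unpack(theta), fmap, p, m)
        try:
            c, low = cho_factor(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        return logdet + np.trace(cho_solve((c, low), S))

    theta0 = np.concatenate([
        np.ones(n_free),                       # unit loadings on mapped items
        np.log(np.maximum(np.diag(S) / 2, 1e-3)),  # sigma2 = half the sample variances
        np.zeros(m * (m + 1) // 2),            # Phi = identity (log-Cholesky)
    ])
    res = optimize.minimize(
        objective, theta0, method="L-BFGS-B",
        options={"maxiter": _MAX_ITER, "ftol": _TOL, "gtol": 1e-8},
    )
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        warnings.warn("ML CFA did not converge; returning starting values",
                      stacklevel=2)
    theta = res.x if converged else theta0
    lam, phi, sigma2, sigma = _implied_cov(*unpack(theta), fmap, p, m)
    loglik = -0.5 * n * (p * np.log(2 * np.pi) + objective(theta))
    return CfaMlFit(
        loadings=lam, factor_cov=phi, residual_variances=sigma2,
        implied_mean=ybar, implied_cov=sigma,
        sample_mean=ybar, sample_cov=S,
        converged=converged, loglik=float(loglik),
    )


def individual_loglik(y, mean, cov):
    """Multivariate-normal log-density of each row of ``y``.

    Returns ``-0.5 (p ln 2pi + ln|cov| + D^2)`` with the Mahalanobis distance
    ``D^2 = (y - mean)' cov^{-1} (y - mean)``; accepts a single vector or a
    matrix of respondents.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    p = y.shape[1]
    try:
        c, low = cho_factor(np.asarray(cov, dtype=float))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance matrix passed to individual_loglik is singular") from err
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    resid = y - np.asarray(mean, dtype=float)
    u = solve_triangular(c, resid.T, lower=low, trans=0 if low else 1)
    d2 = np.sum(u * u, axis=0)
    out = -0.5 * (p * np.log(2 * np.pi) + logdet + d2)
    return out if out.size > 1 else float(out[0])


def person_fit_y1(data: SurveyDataset, fit: CfaMlFit) -> np.ndarray:
    """Likelihood-based person-fit index per respondent.

    ``y1_i = -2 (ll_i(mu, Sigma) - ll_i(ybar, S))``: the respondent's
    log-likelihood deficit under the CFA-implied moments relative to the
    saturated sample moments.
    """
    y = data.responses.astype(float)
    ll_model = np.atleast_1d(individual_loglik(y, fit.implied_mean, fit.implied_cov))
    ll_sat = np.atleast_1d(individual_loglik(y, fit.sample_mean, fit.sample_cov))
    return -2.0 * (ll_model - ll_sat)


def variability_y2(data: SurveyDataset) -> np.ndarray:
    """Within-factor response variance per respondent, averaged over factors."""
    y = data.responses.astype(float)
    fmap = data.item_factor_map
    m = data.n_factors
    pieces = []
    for k in range(m):
        cols = np.flatnonzero(fmap == k)
        if cols.size < 2:
            raise ValueError(f"factor {k} has fewer than 2 items; variance undefined")
        pieces.append(y[:, cols].var(axis=1, ddof=1))
    return np.mean(pieces, axis=0)


def compute_person_indices(data: SurveyDataset, fit: CfaMlFit | None = None,
                           standardize: bool = True) -> PersonIndices:
    """Convenience wrapper: preliminary ML CFA, then both indices."""
    if fit is None:
        fit = fit_ml_cfa(data)
    idx = PersonIndices(y1=person_fit_y1(data, fit), y2=variability_y2(data))
    return standardize_indices(idx) if standardize else idx


def standardize_indices(idx: PersonIndices) -> PersonIndices:
    """Z-score each index across respondents (idempotent; constants recorded).

    A zero-variance index is left unscaled with a warning so degenerate inputs
    do not produce NaNs.
    """
    if idx.standardized:
        return idx
    consts = {}
    out = []
    for name, v in (("y1", idx.y1), ("y2", idx.y2)):
        mu, sd = float(np.mean(v)), float(np.std(v))
        if sd == 0.0:
            warnings.warn(f"index {name} has zero variance; left unscaled",
                          stacklevel=2)
            consts[name] = (mu, 1.0)
            out.append(v - mu)
        else:
            consts[name] = (mu, sd)
            out.append((v - mu) / sd)
    return PersonIndices(y1=out[0], y2=out[1], standardized=True,
                         standardization_constants=consts)
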
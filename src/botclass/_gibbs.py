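"""MCMC kernels for the two-class mixture CFA and the one-class baseline.

Continuous (identity-link) items admit a fully conjugate blocked Gibbs
sampler: the class indicator is drawn with the factor scores integrated out of
the class-1 likelihood (collapsed step), then factor scores, intercepts,
loadings (truncated-normal), residual precisions (gamma) and the factor
precision matrix (Wishart via Bartlett decomposition) follow their exact
conditionals; the logistic class-model coefficients use an adaptive
random-walk Metropolis step.  Binary (logit) and count (log) items lose
conjugacy for the measurement parameters, so those blocks use vectorized
Metropolis-within-Gibbs updates with explicitly sampled factor scores.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import cholesky
from scipy.linalg.lapack import dtrtrs
from scipy.special import gammaln, log_expit, ndtr, ndtri

__all__ = ["run_continuous_chain", "run_glm_chain"]


# ---------------------------------------------------------------- utilities

def _sample_wishart(rng: np.random.Generator, df: float, scale: np.ndarray) -> np.ndarray:
    """Draw from Wishart(df, scale) by the Bartlett decomposition."""
    m = scale.shape[0]
    L = np.linalg.cholesky(scale)
    A = np.zeros((m, m))
    A[np.diag_indices(m)] = np.sqrt(rng.chisquare(df - np.arange(m)))
    if m > 1:
        A[np.tril_indices(m, -1)] = rng.standard_normal(m * (m - 1) // 2)
    LA = L @ A
    return LA @ LA.T


def _truncnorm_positive(rng: np.random.Generator, mean: np.ndarray,
                        sd: np.ndarray) -> np.ndarray:
    """Vectorized draw from N(mean, sd^2) truncated to [0, inf)."""
    a = ndtr(-mean / sd)
    q = a + rng.random(np.shape(mean)) * (1.0 - a)
    q = np.clip(q, 1e-300, 1.0 - 1e-16)
    return mean + sd * ndtri(q)


@lru_cache(maxsize=8)
def _tril_strict(m: int):
    return np.tril_indices(m, -1)


def _mvn_logpdf_rows(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    p = y.shape[1]
    L = np.linalg.cholesky(cov)
    u, info = dtrtrs(L, (y - mean).T, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError("triangular solve failed")
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (p * np.log(2 * np.pi) + logdet + np.einsum("ij,ij->j", u, u))


def _indep_normal_logpdf_rows(y, mean, var):
    return -0.5 * np.sum(np.log(2 * np.pi * var) + (y - mean) ** 2 / var, axis=1)


def _chol_to_theta(L: np.ndarray) -> np.ndarray:
    """Pack a Cholesky factor as (log-diagonal, strict lower triangle)."""
    return np.concatenate([np.log(np.diag(L)), L[_tril_strict(L.shape[0])]])


def _theta_to_chol(theta: np.ndarray, m: int) -> np.ndarray:
    L = np.zeros((m, m))
    L[np.diag_indices(m)] = np.exp(theta[:m])
    if m > 1:
        L[_tril_strict(m)] = theta[m:]
    return L


def _iw_logprior_chol(L: np.ndarray, rate: np.ndarray, df: float) -> float:
    """Inverse-Wishart log prior of Phi = L L' (rate matrix, JAGS convention)."""
    m = L.shape[0]
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Linv, info = dtrtrs(L, np.eye(m), lower=1)
    if info != 0:
        return -np.inf
    phi_inv = Linv.T @ Linv
    return float(-0.5 * (df + m + 1) * logdet - 0.5 * np.sum(phi_inv * rate))


def _logprior_phi(L: np.ndarray, rate: np.ndarray, df: float) -> float:
    """Inverse-Wishart log prior of Phi plus the log-Cholesky Jacobian."""
    m = L.shape[0]
    jac = np.sum((m - np.arange(m) + 1) * np.log(np.diag(L)))
    return _iw_logprior_chol(L, rate, df) + jac


class _AdaptiveRW:
    """Haario-style adaptive random-walk proposal for a small parameter block."""

    def __init__(self, dim: int, target: float = 0.3):
        self.dim = dim
        self.target = target
        self.log_scale = np.log(2.38 / np.sqrt(dim))
        self.mean = np.zeros(dim)
        self.cov = np.eye(dim)
        self.count = 0
        self._chol = None

    def propose(self, rng, current):
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.cov + 1e-8 * np.eye(self.dim))
        return current + np.exp(self.log_scale) * (
            self._chol @ rng.standard_normal(self.dim))

    def adapt(self, accepted: bool, draw: np.ndarray):
        self.count += 1
        w = 1.0 / (self.count + 10)
        self.log_scale += w * ((1.0 if accepted else 0.0) - self.target)
        delta = draw - self.mean
        self.mean = self.mean + w * delta
        self.cov = self.cov + w * (np.outer(delta, delta) - self.cov)
        self._chol = None


def _metropolis_beta(rng, beta, labels_human, X, prior_var, adapt: _AdaptiveRW,
                     adapting: bool, n_steps: int = 3):
    """RW Metropolis on the logistic class-model coefficients.

    ``labels_human`` is +1 for class 1 (human), -1 for class 2, so the
    log-likelihood is ``sum log_expit(s * X beta)``.
    """
    s = labels_human
    def logpost(b):
        return np.sum(log_expit(s * (X @ b))) - 0.5 * np.sum(b * b) / prior_var
    lp = logpost(beta)
    for _ in range(n_steps):
        prop = adapt.propose(rng, beta)
        lp_prop = logpost(prop)
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            beta, lp = prop, lp_prop
        if adapting:
            adapt.adapt(accept, beta)
    return beta


# ------------------------------------------------- continuous-family kernel

def run_continuous_chain(
    y: np.ndarray,
    X: np.ndarray | None,
    fmap: np.ndarray,
    free_items: np.ndarray,
    priors,
    n_iter: int,
    burnin: int,
    rng: np.random.Generator,
    init: dict,
    mixture: bool = True,
    thin: int = 1,
) -> dict:
    """One MCMC chain for continuous (identity-link) items.

    Returns kept draws of all monitored parameters plus the per-person
    Rao-Blackwellized posterior bot probability averaged over kept sweeps.
    """
    n, p = y.shape
    m = int(fmap.max()) + 1
    tril = np.tril_indices(m)
    fcols = fmap  # item -> factor index

    tau1 = init["tau1"].copy()
    lam = init["lam"].copy()           # full p-vector, scaling items == 1
    sigma1 = init["sigma1"].copy()
    phi = init["phi"].copy()
    phi_inv = np.linalg.inv(phi)
    tau2 = init["tau2"].copy()
    sigma2 = init["sigma2"].copy()
    beta = init["beta"].copy()
    eta = init.get("eta", np.zeros((n, m))).copy()
    is_bot = np.zeros(n, dtype=bool)

    w_df = priors.wishart_df + n
    w_rate0 = priors.wishart_scale  # JAGS-style rate matrix of the Wishart prior
    g_shape, g_rate = priors.sigma_shape, priors.sigma_rate
    tau_prec0 = 1.0 / priors.tau_var
    lam_prec0 = 1.0 / priors.loading_var

    adapt = _AdaptiveRW(3)
    adapt_phi = _AdaptiveRW(m * (m + 1) // 2, target=0.25)
    s_scale = np.full(m, 0.2)   # per-factor scale-move step sizes
    ix_items = np.ix_(fcols, fcols)
    diag_p = np.diag_indices(p)
    eye_m = np.eye(m)
    eye_p = np.eye(p)
    free_by_factor = [free_items[fcols[free_items] == k] for k in range(m)]
    n_keep = (n_iter - burnin) // thin
    out = {
        "tau1": np.empty((n_keep, p)), "lam": np.empty((n_keep, p)),
        "sigma1": np.empty((n_keep, p)), "tau2": np.empty((n_keep, p)),
        "sigma2": np.empty((n_keep, p)), "phi": np.empty((n_keep, len(tril[0]))),
        "beta": np.empty((n_keep, 3)),
    }
    pbot_sum = np.zeros(n)
    kept = 0
    occupied = 0  # kept sweeps in which class 2 is non-empty

    for it in range(n_iter):
        # -- class indicators, factor scores integrated out of class 1
        cov1 = lam[:, None] * lam[None, :] * phi[ix_items]
        cov1[diag_p] += sigma1
        logf1 = _mvn_logpdf_rows(y, tau1, cov1)
        if mixture:
            logf2 = _indep_normal_logpdf_rows(y, tau2, sigma2)
            lin = X @ beta
            lp1 = log_expit(lin) + logf1
            lp2 = log_expit(-lin) + logf2
            norm = np.logaddexp(lp1, lp2)
            pbot = np.exp(lp2 - norm)
            is_bot = rng.random(n) < pbot
        humans = ~is_bot
        n1 = int(humans.sum())
        n2 = n - n1

        # -- collapsed Metropolis step on Phi (factor scores integrated out):
        #    the conjugate Wishart step below moves Phi only through eta, which
        #    mixes slowly; this marginal move decorrelates the factor
        #    (co)variances.  Reuses logf1 computed above.
        if n1:
            yh_block = y[humans]
            ll_cur = float(logf1[humans].sum())

            def _marg_ll(lam_v, phi_v):
                cov = lam_v[:, None] * lam_v[None, :] * phi_v[ix_items]
                cov[diag_p] += sigma1
                try:
                    return float(_mvn_logpdf_rows(yh_block, tau1, cov).sum())
                except np.linalg.LinAlgError:
                    return -np.inf

            # (a) generic adaptive proposals on the log-Cholesky of Phi
            L_cur = np.linalg.cholesky(phi)
            theta_cur = _chol_to_theta(L_cur)
            pri_cur = _logprior_phi(L_cur, w_rate0, priors.wishart_df)
            for _ in range(2):
                theta_prop = adapt_phi.propose(rng, theta_cur)
                L_prop = _theta_to_chol(theta_prop, m)
                phi_prop = L_prop @ L_prop.T
                ll_prop = _marg_ll(lam, phi_prop)
                pri_prop = _logprior_phi(L_prop, w_rate0, priors.wishart_df)
                accept_phi = np.log(rng.random()) < (ll_prop + pri_prop
                                                     - ll_cur - pri_cur)
                if accept_phi:
                    phi, L_cur, theta_cur = phi_prop, L_prop, theta_prop
                    ll_cur, pri_cur = ll_prop, pri_prop
                if it < burnin:
                    adapt_phi.adapt(accept_phi, theta_cur)

            # (b) one multiplicative scale move per factor: rescale the factor's
            #     (co)variances and divide its free loadings, travelling along
            #     the scale ridge that one-at-a-time updates cross slowly
            iw_cur = _iw_logprior_chol(L_cur, w_rate0, priors.wishart_df)
            for k in range(m):
                fk = free_by_factor[k]
                c = float(np.exp(s_scale[k] * rng.standard_normal()))
                lam_prop = lam.copy()
                lam_prop[fk] = lam[fk] / c
                dvec = np.ones(m)
                dvec[k] = c
                phi_prop = phi * np.outer(dvec, dvec)
                L_prop = dvec[:, None] * L_cur
                ll_prop = _marg_ll(lam_prop, phi_prop)
                iw_prop = _iw_logprior_chol(L_prop, w_rate0, priors.wishart_df)
                dlog = (ll_prop - ll_cur + iw_prop - iw_cur
                        - 0.5 * lam_prec0 * float(np.sum(lam_prop[fk] ** 2
                                                         - lam[fk] ** 2))
                        + (m + 1 - fk.size) * np.log(c))
                accept_sc = np.log(rng.random()) < dlog
                if accept_sc:
                    lam, phi, L_cur = lam_prop, phi_prop, L_prop
                    ll_cur, iw_cur = ll_prop, iw_prop
                if it < burnin:
                    step = 1.0 / (1.0 + it) ** 0.6
                    s_scale[k] *= np.exp(step * (float(accept_sc) - 0.44))
            Linv, _ = dtrtrs(L_cur, eye_m, lower=1)
            phi_inv = Linv.T @ Linv

            # -- collapsed intercept draw (factor scores integrated out):
            #    conditional on eta, tau1 trades off against the mean factor
            #    score along a flat ridge; in the eta-marginal model the
            #    Gaussian conditional of tau1 is tight and conjugate.
            covf = lam[:, None] * lam[None, :] * phi[ix_items]
            covf[diag_p] += sigma1
            Lf = np.linalg.cholesky(covf)
            Lfi, _ = dtrtrs(Lf, eye_p, lower=1)
            s_inv = Lfi.T @ Lfi
            prec_t = n1 * s_inv + tau_prec0 * eye_p
            rhs_t = s_inv @ yh_block.sum(axis=0) + tau_prec0 * priors.tau_mean
            Lq = np.linalg.cholesky(prec_t)
            half_t, _ = dtrtrs(Lq, rhs_t, lower=1)
            mean_t, _ = dtrtrs(Lq, half_t, lower=1, trans=1)
            noise_t, _ = dtrtrs(Lq, rng.standard_normal(p), lower=1, trans=1)
            tau1 = mean_t + noise_t

        # -- factor scores (exact conditional; simple structure makes
        #    Lambda' D^-1 Lambda diagonal)
        w = lam / sigma1
        d = np.bincount(fcols, weights=lam * w, minlength=m)
        P = phi_inv + np.diag(d)
        Lp = np.linalg.cholesky(P)
        if n1:
            resid = y[humans] - tau1
            rhs = np.empty((m, n1))
            for k in range(m):
                cols = fcols == k
                rhs[k] = resid[:, cols] @ w[cols]
            half, _ = dtrtrs(Lp, rhs, lower=1)
            mean, _ = dtrtrs(Lp, half, lower=1, trans=1)
            noise, _ = dtrtrs(Lp, rng.standard_normal((m, n1)), lower=1, trans=1)
            eta[humans] = (mean + noise).T
        if n2:
            Lphi = L_cur if n1 else np.linalg.cholesky(phi)
            eta[is_bot] = rng.standard_normal((n2, m)) @ Lphi.T

        # -- factor precision (Wishart, JAGS rate parameterization)
        scatter = w_rate0 + eta.T @ eta
        phi_inv = _sample_wishart(rng, w_df, np.linalg.inv(scatter))
        phi = np.linalg.inv(phi_inv)
        phi = 0.5 * (phi + phi.T)

        # -- class-1 loadings and residual precisions (humans only; the
        #    intercepts were drawn from their collapsed conditional above)
        if n1:
            yh = y[humans]
            U = eta[humans][:, fcols]
            r2 = yh - tau1
            su2 = np.sum(U * U, axis=0)
            sur = np.sum(U * r2, axis=0)
            prec_l = su2 / sigma1 + lam_prec0
            mean_l = (sur / sigma1) / prec_l
            lam[free_items] = _truncnorm_positive(
                rng, mean_l[free_items], 1.0 / np.sqrt(prec_l[free_items]))

            ss = np.sum((r2 - lam * U) ** 2, axis=0)
            sigma1 = 1.0 / rng.gamma(g_shape + 0.5 * n1, 1.0 / (g_rate + 0.5 * ss))

        # -- class-2 (intercept-only) parameters.  When the class is empty the
        #    update is skipped (a valid Gibbs kernel): redrawing from the prior
        #    would park the intercepts far from the response scale and make the
        #    empty class an absorbing state.
        if mixture and n2:
            yb = y[is_bot]
            prec = n2 / sigma2 + tau_prec0
            mean = (yb.sum(axis=0) / sigma2 + priors.tau_mean * tau_prec0) / prec
            tau2 = mean + rng.standard_normal(p) / np.sqrt(prec)
            ss2 = np.sum((yb - tau2) ** 2, axis=0)
            sigma2 = 1.0 / rng.gamma(g_shape + 0.5 * n2, 1.0 / (g_rate + 0.5 * ss2))

        # -- logistic class model
        if mixture:
            s = np.where(is_bot, -1.0, 1.0)
            beta = _metropolis_beta(rng, beta, s, X, priors.beta_var, adapt,
                                    adapting=it < burnin)

        if it >= burnin and (it - burnin) % thin == 0:
            out["tau1"][kept] = tau1
            out["lam"][kept] = lam
            out["sigma1"][kept] = sigma1
            out["tau2"][kept] = tau2
            out["sigma2"][kept] = sigma2
            out["phi"][kept] = phi[tril]
            out["beta"][kept] = beta
            if mixture:
                pbot_sum += pbot
                occupied += int(n2 > 0)
            kept += 1

    out["pbot"] = pbot_sum / max(kept, 1)
    out["occupancy"] = occupied / max(kept, 1)
    return out


# ------------------------------------------------ binary / count families

def _ll_matrix(y, mu, family):
    if family == "binary":
        return y * log_expit(mu) + (1.0 - y) * log_expit(-mu)
    if family == "count":
        return y * mu - np.exp(mu) - gammaln(y + 1.0)
    raise ValueError(f"unknown family {family!r}")


def run_glm_chain(
    y: np.ndarray,
    X: np.ndarray | None,
    fmap: np.ndarray,
    free_items: np.ndarray,
    priors,
    n_iter: int,
    burnin: int,
    rng: np.random.Generator,
    init: dict,
    family: str,
    mixture: bool = True,
    thin: int = 1,
    fix_class2_intercepts: bool = False,
) -> dict:
    """Metropolis-within-Gibbs chain for binary (logit) or count (log) items.

    Factor scores are sampled explicitly; measurement blocks use per-item
    random-walk proposals with Robbins-Monro scale adaptation during burn-in.
    """
    n, p = y.shape
    m = int(fmap.max()) + 1
    tril = np.tril_indices(m)
    y = y.astype(float)

    tau1 = init["tau1"].copy()
    lam = init["lam"].copy()
    phi = init["phi"].copy()
    phi_inv = np.linalg.inv(phi)
    tau2 = init["tau2"].copy()
    beta = init["beta"].copy()
    eta = init.get("eta", np.zeros((n, m))).copy()
    is_bot = np.zeros(n, dtype=bool)

    s_eta = np.full(n, 0.5)
    s_tau1 = np.full(p, 0.2)
    s_lam = np.full(p, 0.2)
    s_tau2 = np.full(p, 0.2)
    adapt = _AdaptiveRW(3)
    tau_prec0 = 1.0 / priors.tau_var
    lam_prec0 = 1.0 / priors.loading_var

    n_keep = (n_iter - burnin) // thin
    out = {
        "tau1": np.empty((n_keep, p)), "lam": np.empty((n_keep, p)),
        "tau2": np.empty((n_keep, p)), "phi": np.empty((n_keep, len(tril[0]))),
        "beta": np.empty((n_keep, 3)),
    }
    pbot_sum = np.zeros(n)
    kept = 0
    occupied = 0

    def rw_update(scale, accepted, it):
        # Robbins-Monro toward 0.44 acceptance for scalar blocks
        step = 1.0 / (1.0 + it) ** 0.6
        return scale * np.exp(step * (accepted - 0.44))

    for it in range(n_iter):
        adapting = it < burnin
        mu1 = tau1 + lam * eta[:, fmap]
        ll1_rows = _ll_matrix(y, mu1, family).sum(axis=1)
        if mixture:
            ll2_rows = _ll_matrix(y, tau2, family).sum(axis=1)
            lin = X @ beta
            lp1 = log_expit(lin) + ll1_rows
            lp2 = log_expit(-lin) + ll2_rows
            norm = np.logaddexp(lp1, lp2)
            pbot = np.exp(lp2 - norm)
            is_bot = rng.random(n) < pbot
        humans = ~is_bot
        n2 = int(is_bot.sum())

        # factor scores: MH for humans, exact prior draw for bots
        prop = eta + s_eta[:, None] * rng.standard_normal((n, m))
        mu_prop = tau1 + lam * prop[:, fmap]
        dll = (_ll_matrix(y, mu_prop, family) - _ll_matrix(y, mu1, family)).sum(axis=1)
        dprior = -0.5 * (np.einsum("ij,jk,ik->i", prop, phi_inv, prop)
                         - np.einsum("ij,jk,ik->i", eta, phi_inv, eta))
        acc = (np.log(rng.random(n)) < dll + dprior) & humans
        eta[acc] = prop[acc]
        if n2:
            Lphi = cholesky(phi, lower=True)
            eta[is_bot] = rng.standard_normal((n2, m)) @ Lphi.T
        if adapting:
            s_eta = np.where(humans, rw_update(s_eta, acc.astype(float), it), s_eta)

        scatter = priors.wishart_scale + eta.T @ eta
        phi_inv = _sample_wishart(rng, priors.wishart_df + n, np.linalg.inv(scatter))
        phi = np.linalg.inv(phi_inv)
        phi = 0.5 * (phi + phi.T)

        # class-1 measurement parameters, per-item MH over humans
        yh, etah = y[humans], eta[humans]
        U = etah[:, fmap]
        for name in ("tau1", "lam"):
            cur = tau1 if name == "tau1" else lam
            scale = s_tau1 if name == "tau1" else s_lam
            prop_v = cur + scale * rng.standard_normal(p)
            if name == "lam":
                prop_v[~np.isin(np.arange(p), free_items)] = 1.0
            mu_cur = tau1 + lam * U
            if name == "tau1":
                mu_prop = prop_v + lam * U
                dprior_v = -0.5 * tau_prec0 * (prop_v ** 2 - cur ** 2)
            else:
                mu_prop = tau1 + prop_v * U
                dprior_v = np.where(prop_v < 0, -np.inf,
                                    -0.5 * lam_prec0 * (prop_v ** 2 - cur ** 2))
            dll_v = (_ll_matrix(yh, mu_prop, family)
                     - _ll_matrix(yh, mu_cur, family)).sum(axis=0) + dprior_v
            acc_v = np.log(rng.random(p)) < dll_v
            if name == "tau1":
                tau1 = np.where(acc_v, prop_v, tau1)
                if adapting:
                    s_tau1 = rw_update(s_tau1, acc_v.astype(float), it)
            else:
                acc_v &= np.isin(np.arange(p), free_items)
                lam = np.where(acc_v, prop_v, lam)
                if adapting:
                    s_lam = rw_update(s_lam, acc_v.astype(float), it)

        # class-2 intercepts; skipped when the class is empty (see the
        # continuous kernel for the rationale)
        if mixture and not fix_class2_intercepts and n2:
            yb = y[is_bot]
            prop_v = tau2 + s_tau2 * rng.standard_normal(p)
            dll_v = (_ll_matrix(yb, prop_v, family)
                     - _ll_matrix(yb, tau2, family)).sum(axis=0)
            dll_v += -0.5 * tau_prec0 * (prop_v ** 2 - tau2 ** 2)
            acc_v = np.log(rng.random(p)) < dll_v
            tau2 = np.where(acc_v, prop_v, tau2)
            if adapting:
                s_tau2 = rw_update(s_tau2, acc_v.astype(float), it)

        if mixture:
            s = np.where(is_bot, -1.0, 1.0)
            beta = _metropolis_beta(rng, beta, s, X, priors.beta_var, adapt,
                                    adapting=adapting)

        if it >= burnin and (it - burnin) % thin == 0:
            out["tau1"][kept] = tau1
            out["lam"][kept] = lam
            out["tau2"][kept] = tau2
            out["phi"][kept] = phi[tril]
            out["beta"][kept] = beta
            if mixture:
                pbot_sum += pbot
                occupied += int(n2 > 0)
            kept += 1

    out["pbot"] = pbot_sum / max(kept, 1)
    out["occupancy"] = occupied / max(kept, 1)
    return out
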
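"""Convergence diagnostics and simulation scoring metrics.

The split-Rhat and effective-sample-size implementations follow the
rank-normalization recipe of Vehtari, Gelman, Simpson, Carpenter & Buerkner
(2021): chains are split in half, draws are replaced by normal scores of their
pooled fractional ranks, and the potential scale reduction factor / Geyer
initial-monotone autocorrelation sum are computed on the transformed chains.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.fft import next_fast_len
from scipy.special import ndtri
from scipy.stats import rankdata

__all__ = [
    "split_rhat",
    "effective_sample_size",
    "sensitivity_specificity",
    "percent_bias",
    "beta_significance",
]


def _split_chains(chains: np.ndarray) -> np.ndarray:
    c, n = chains.shape
    half = n // 2
    return np.vstack([chains[:, :half], chains[:, half:2 * half]])


def _z_scale(ary: np.ndarray) -> np.ndarray:
    """Normal scores of pooled fractional ranks (Blom's 3/8 offset)."""
    rank = rankdata(ary, method="average").reshape(ary.shape)
    return ndtri((rank - 0.375) / (ary.size + 0.25))


def _rhat_basic(chains: np.ndarray) -> float:
    c, n = chains.shape
    within = np.mean(np.var(chains, axis=1, ddof=1))
    between = n * np.var(np.mean(chains, axis=1), ddof=1)
    var_plus = (n - 1) / n * within + between / n
    return float(np.sqrt(var_plus / within))


def split_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws); at least 2 chains and 4 draws
    per chain are required.  The statistic is the maximum of the bulk
    (rank-normalized) and tail (folded) split-Rhat; values below 1.01 are
    conventionally taken as converged.  Chains with zero total variance return
    1.0 by convention, with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    if np.ptp(chains) == 0.0:
        warnings.warn("all draws identical; returning Rhat = 1.0", stacklevel=2)
        return 1.0
    split = _split_chains(chains)
    bulk = _rhat_basic(_z_scale(split))
    folded = _rhat_basic(_z_scale(np.abs(split - np.median(split))))
    return max(bulk, folded)


def _autocov(chains: np.ndarray) -> np.ndarray:
    """Per-chain autocovariance at all lags (biased, FFT-based)."""
    c, n = chains.shape
    size = next_fast_len(2 * n)
    demeaned = chains - chains.mean(axis=1, keepdims=True)
    f = np.fft.rfft(demeaned, n=size, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), n=size, axis=1)[:, :n].real
    return acov / n


def _ess_core(chains: np.ndarray) -> float:
    c, n = chains.shape
    acov = _autocov(chains)
    chain_means = chains.mean(axis=1)
    mean_var = np.mean(acov[:, 0]) * n / (n - 1.0)
    var_plus = mean_var * (n - 1.0) / n
    if c > 1:
        var_plus += np.var(chain_means, ddof=1)
    if var_plus == 0.0:
        return float(c * n)

    rho_hat_t = np.zeros(n)
    rho_hat_even = 1.0
    rho_hat_t[0] = rho_hat_even
    rho_hat_odd = 1.0 - (mean_var - np.mean(acov[:, 1])) / var_plus
    rho_hat_t[1] = rho_hat_odd
    # Geyer initial positive sequence
    t = 1
    while t < n - 3 and (rho_hat_even + rho_hat_odd) > 0.0:
        rho_hat_even = 1.0 - (mean_var - np.mean(acov[:, t + 1])) / var_plus
        rho_hat_odd = 1.0 - (mean_var - np.mean(acov[:, t + 2])) / var_plus
        if (rho_hat_even + rho_hat_odd) >= 0:
            rho_hat_t[t + 1] = rho_hat_even
            rho_hat_t[t + 2] = rho_hat_odd
        t += 2
    max_t = t - 2
    if rho_hat_even > 0:
        rho_hat_t[max_t + 1] = rho_hat_even
    # Geyer initial monotone sequence
    t = 1
    while t <= max_t - 2:
        if (rho_hat_t[t + 1] + rho_hat_t[t + 2]) > (rho_hat_t[t - 1] + rho_hat_t[t]):
            rho_hat_t[t + 1] = (rho_hat_t[t - 1] + rho_hat_t[t]) / 2.0
            rho_hat_t[t + 2] = rho_hat_t[t + 1]
        t += 2
    ess = c * n
    tau_hat = -1.0 + 2.0 * np.sum(rho_hat_t[: max_t + 1]) + rho_hat_t[max_t + 1]
    tau_hat = max(tau_hat, 1.0 / np.log10(ess))
    return float(ess / tau_hat)


def effective_sample_size(chains: np.ndarray) -> float:
    """Bulk effective sample size of rank-normalized split chains.

    Super-efficient values (ESS above the number of draws) are possible for
    anticorrelated chains and are returned as-is.  Zero-variance chains return
    the nominal draw count with a warning.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 4:
        raise ValueError("need >= 2 chains with >= 4 draws each")
    if np.ptp(chains) == 0.0:
        warnings.warn("all draws identical; returning nominal size", stacklevel=2)
        return float(chains.size)
    return _ess_core(_z_scale(_split_chains(chains)))


def sensitivity_specificity(true_labels, predicted) -> tuple[float, float]:
    """True-positive and true-negative rates with bot as the positive class.

    Undefined rates (no true bots, or no true humans) are returned as NaN
    rather than zero.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted)
    if t.shape != p.shape:
        raise ValueError("label vectors must have the same length")
    legal = {"human", "bot"}
    if not (set(np.unique(t)) <= legal and set(np.unique(p)) <= legal):
        raise ValueError("labels must be 'human' or 'bot'")
    tp = np.sum((t == "bot") & (p == "bot"))
    fn = np.sum((t == "bot") & (p == "human"))
    tn = np.sum((t == "human") & (p == "human"))
    fp = np.sum((t == "human") & (p == "bot"))
    sens = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    return float(sens), float(spec)


def percent_bias(estimates, truth) -> float:
    """Mean percent deviation of estimates from their population values.

    ``mean(100 * (est - true) / true)`` over all entries; entries with zero
    truth are excluded with a warning (percent bias is undefined there).
    """
    est = np.asarray(estimates, dtype=float).ravel()
    true = np.asarray(truth, dtype=float).ravel()
    if est.shape != true.shape:
        raise ValueError("estimates and truth must align")
    keep = true != 0.0
    if not keep.all():
        warnings.warn("excluding parameters with zero population value",
                      stacklevel=2)
    if not keep.any():
        return np.nan
    return float(np.mean(100.0 * (est[keep] - true[keep]) / true[keep]))


def beta_significance(draws, prob: float = 0.95) -> np.ndarray:
    """Whether each coefficient's central credible interval excludes zero.

    ``draws`` is (..., n_coef); the interval is computed over all leading axes.
    """
    flat = np.asarray(draws, dtype=float).reshape(-1, np.shape(draws)[-1])
    lo = np.quantile(flat, (1 - prob) / 2, axis=0)
    hi = np.quantile(flat, 1 - (1 - prob) / 2, axis=0)
    return (lo > 0) | (hi < 0)
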
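"""Adaptive Metropolis-within-Gibbs and convergence diagnostics.

A small, generic componentwise Gaussian random-walk sampler: proposal scales
adapt toward a 0.2-0.5 acceptance band during burn-in and are frozen
afterwards (preserving detailed balance for the retained draws).  Bounded
components use reflection at the bounds, which keeps the proposal symmetric.

Diagnostics are the plain split-R-hat (floored at 1) and an
autocorrelation-based effective sample size truncated at the first negative
pair sum of autocorrelations.
"""
from __future__ import annotations

import numpy as np

__all__ = ["adaptive_mwg", "split_rhat", "effective_sample_size"]


def _reflect(x: float, lo: float, hi: float) -> float:
    if not np.isfinite(lo) and not np.isfinite(hi):
        return x
    span = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
        if span <= 0:
            return lo
    return x


def adaptive_mwg(log_target, x0, *, n_burn: int, n_iter: int, thin: int,
                 rng: np.random.Generator, scales=None, bounds=None,
                 adapt_window: int = 50, accept_band=(0.2, 0.5)):
    """Sample ``log_target`` with an adaptive componentwise random walk.

    Parameters
    ----------
    log_target : callable(ndarray) -> float
        Log-density up to a constant; ``-inf`` outside the support.
    x0 : ndarray
        Starting point (must have finite log-density).
    bounds : list of (lo, hi) or None
        Reflection bounds per component (use ``-inf``/``inf`` for none).

    Returns
    -------
    draws : ndarray of shape (n_iter // thin, len(x0))
    info : dict with final proposal ``scales`` and per-component ``accept_rate``.
    """
    x = np.array(x0, dtype=float)
    d = x.size
    lp = log_target(x)
    if not np.isfinite(lp):
        raise ValueError(f"non-finite log-target at the initial point: {x!r}")
    scales = np.ones(d) if scales is None else np.array(scales, dtype=float)
    if bounds is None:
        bounds = [(-np.inf, np.inf)] * d
    n_keep = n_iter // thin
    draws = np.empty((n_keep, d))
    acc = np.zeros(d)
    acc_win = np.zeros(d)
    n_prop = 0

    kept = 0
    for it in range(n_burn + n_iter):
        for j in range(d):
            prop = x[j] + scales[j] * rng.standard_normal()
            prop = _reflect(prop, *bounds[j])
            xj = x[j]
            x[j] = prop
            lp_new = log_target(x)
            if np.log(rng.random()) < lp_new - lp:
                lp = lp_new
                acc_win[j] += 1
                if it >= n_burn:
                    acc[j] += 1
            else:
                x[j] = xj
        n_prop += 1
        if it < n_burn and n_prop % adapt_window == 0:
            rate = acc_win / adapt_window
            scales[rate > accept_band[1]] *= 1.5
            scales[rate < accept_band[0]] /= 1.5
            acc_win[:] = 0.0
        if it >= n_burn and (it - n_burn) % thin == thin - 1:
            draws[kept] = x
            kept += 1
    return draws[:kept], {"scales": scales, "accept_rate": acc / max(n_iter, 1)}


def split_rhat(chains) -> float:
    """Plain split-R-hat for one parameter; ``chains`` is (n_chains, n_draws).

    Each chain is split in half before the between/within comparison; the
    statistic is floored at 1.
    """
    c = np.asarray(chains, dtype=float)
    if c.ndim != 2 or c.shape[0] < 2:
        raise ValueError("need at least two chains of draws")
    n = c.shape[1] // 2
    if n < 2:
        raise ValueError("need at least 4 draws per chain")
    halves = np.concatenate([c[:, :n], c[:, n:2 * n]], axis=0)
    means = halves.mean(axis=1)
    B = n * means.var(ddof=1)
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return max(1.0, float(np.sqrt(var_plus / W)))


def effective_sample_size(samples) -> float:
    """Autocorrelation ESS for one parameter (chains pooled if 2-D).

    Uses Geyer-style truncation at the first negative sum of an even/odd
    autocorrelation pair.  A constant chain is degenerate and reports 0.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    m, n = x.shape
    if n < 4:
        raise ValueError("need more draws for an ESS estimate")
    xc = x - x.mean(axis=1, keepdims=True)
    var = (xc ** 2).mean()
    if var == 0.0:
        return 0.0
    # FFT autocovariance averaged over chains
    size = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real / n
    rho = acov.mean(axis=0) / acov[:, 0].mean()
    tau = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += pair
        t += 2
    return float(m * n / (1.0 + 2.0 * tau))
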
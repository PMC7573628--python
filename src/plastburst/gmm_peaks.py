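"""Gaussian-mixture peak detection in (weighted) Ks distributions.

Ks values are restricted to the 0.05–5 window (inclusive) to avoid both
near-identical pairs and saturated estimates, then fitted with univariate
unequal-variance Gaussian mixtures by weighted EM.  The number of
components is chosen either by BIC (k = 1..9, mclust-style
BIC = 2 lnL - (3k-1) ln n, maximised) or by a sequential parametric
bootstrap of the likelihood-ratio statistic (k vs k+1, default 1000
replicates, alpha = 0.01).  95% confidence intervals around peak means
come from a parametric bootstrap with components matched by sorted means.

Sample weights (from duplication-node weighting) multiply the EM
responsibilities; the effective sample size sum(w) replaces n in the BIC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

__all__ = [
    "GMMFit",
    "PeakSet",
    "filter_ks",
    "em_fit",
    "select_k_bic",
    "select_k_bootstrap",
    "peak_confidence_intervals",
    "mixture_density",
    "sample_from_fit",
]

KS_WINDOW = (0.05, 5.0)
# control parameters, as used: convergence epsilon on the lnL gain,
# iteration cap, and restart cap on component collapse
EM_EPSILON = 1e-10
EM_MAX_ITER = 1000
EM_MAX_RESTARTS = 20


@dataclass
class GMMFit:
    k: int
    proportions: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    bic: float
    n_eff: float
    converged: bool
    n_iter: int = 0

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if abs(self.proportions.sum() - 1.0) > 1e-9:
            raise ValueError("mixing proportions must sum to 1")
        if (self.sds <= 0).any():
            raise ValueError("component sd must be positive")
        order = np.argsort(self.means)
        self.proportions = self.proportions[order]
        self.means = self.means[order]
        self.sds = self.sds[order]


@dataclass
class PeakSet:
    means: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    proportions: np.ndarray
    n_discarded: int = 0


def filter_ks(samples, weights=None, lo: float = KS_WINDOW[0], hi: float = KS_WINDOW[1]):
    """Keep lo <= ks <= hi (both ends inclusive); weights follow samples."""
    x = np.asarray(samples, dtype=float)
    keep = (x >= lo) & (x <= hi)
    if weights is None:
        return x[keep]
    w = np.asarray(weights, dtype=float)
    return x[keep], w[keep]


def _log_normal_pdf(x: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    # x: (n,), mu/sd: (k,) -> (n, k)
    z = (x[:, None] - mu[None, :]) / sd[None, :]
    return -0.5 * z * z - np.log(sd[None, :]) - 0.5 * math.log(2 * math.pi)


def _weighted_loglik(x, w, lam, mu, sd) -> float:
    logp = _log_normal_pdf(x, mu, sd) + np.log(lam[None, :])
    m = logp.max(axis=1)
    return float((w * (m + np.log(np.exp(logp - m[:, None]).sum(axis=1)))).sum())


def _init_params(x: np.ndarray, w: np.ndarray, k: int, rng: Optional[np.random.Generator]):
    """Quantile-spaced means, pooled sd, equal proportions; optional jitter."""
    qs = (np.arange(k) + 0.5) / k
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    mu = np.interp(qs, cw, x[order])
    mean = float((w * x).sum() / w.sum())
    var = float((w * (x - mean) ** 2).sum() / w.sum())
    sd = np.full(k, max(math.sqrt(var), 1e-3))
    if rng is not None:
        mu = mu + rng.normal(0.0, max(math.sqrt(var), 1e-3) / 2, size=k)
        sd = sd * np.exp(rng.normal(0.0, 0.3, size=k))
    lam = np.full(k, 1.0 / k)
    return lam, mu, sd


def em_fit(
    samples,
    weights=None,
    k: int = 1,
    init=None,
    tol: float = EM_EPSILON,
    max_iter: int = EM_MAX_ITER,
    seed: Optional[int] = None,
    max_restarts: int = EM_MAX_RESTARTS,
) -> GMMFit:
    """Weighted EM for a k-component unequal-variance univariate mixture.

    The weighted log-likelihood is non-decreasing across iterations;
    convergence is declared when the gain drops below ``tol``.  Component
    collapse (sd -> 0 or an empty component) triggers a restart from a
    perturbed initialisation; after ``max_restarts`` the best non-collapsed
    state is returned flagged unconverged.
    """
    x = np.asarray(samples, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("samples must be a non-empty 1-d array")
    n_eff = float(w.sum())
    if n_eff < 3 * k:
        raise ValueError(f"effective sample size {n_eff:.1f} < 3k = {3 * k}")
    if k == 1:
        mean = float((w * x).sum() / n_eff)
        var = float((w * (x - mean) ** 2).sum() / n_eff)
        sd = math.sqrt(max(var, 1e-300))
        ll = _weighted_loglik(x, w, np.array([1.0]), np.array([mean]), np.array([sd]))
        return GMMFit(1, np.array([1.0]), np.array([mean]), np.array([sd]),
                      ll, 2 * ll - 2 * math.log(n_eff), n_eff, True, 0)

    rng = np.random.default_rng(seed)
    sd_floor = 1e-6 * max(float(x.std()), 1e-6)

    for attempt in range(max_restarts + 1):
        if init is not None and attempt == 0:
            lam, mu, sd = (np.asarray(v, dtype=float).copy() for v in init)
        else:
            lam, mu, sd = _init_params(x, w, k, rng if attempt else None)
        prev = -np.inf
        collapsed = False
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            logp = _log_normal_pdf(x, mu, sd) + np.log(np.maximum(lam[None, :], 1e-300))
            m = logp.max(axis=1)
            dens = np.exp(logp - m[:, None])
            tot = dens.sum(axis=1)
            ll = float((w * (m + np.log(tot))).sum())
            resp = dens / tot[:, None] * w[:, None]
            wk = resp.sum(axis=0)
            if (wk < 1e-12 * n_eff).any():
                collapsed = True
                break
            lam = wk / n_eff
            mu = (resp * x[:, None]).sum(axis=0) / wk
            sd = np.sqrt((resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / wk)
            if (sd < sd_floor).any():
                collapsed = True
                break
            if ll - prev < tol and it > 1:
                converged = True
                prev = ll
                break
            prev = ll
        if not collapsed:
            ll = _weighted_loglik(x, w, lam, mu, sd)
            bic = 2 * ll - (3 * k - 1) * math.log(n_eff)
            return GMMFit(k, lam, mu, sd, ll, bic, n_eff, converged, it)
        init = None  # perturbed restart
    # all restarts collapsed: fall back to a single-component description
    fit1 = em_fit(x, w, k=1)
    lam = np.full(k, 1.0 / k)
    mu = np.full(k, fit1.means[0]) + np.linspace(-1, 1, k) * fit1.sds[0] * 1e-3
    sd = np.full(k, fit1.sds[0])
    ll = _weighted_loglik(x, w, lam, mu, sd)
    return GMMFit(k, lam, mu, sd, ll, 2 * ll - (3 * k - 1) * math.log(n_eff),
                  n_eff, False, 0)


def select_k_bic(
    samples,
    weights=None,
    kmax: int = 9,
    seed: Optional[int] = None,
    n_init: int = 3,
) -> GMMFit:
    """Fit k = 1..kmax and return the fit maximising the BIC.

    ``n_init`` random EM initialisations per k guard against local
    maxima; kmax is lowered automatically when the sample is too small.
    """
    x = np.asarray(samples, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    n_eff = float(w.sum())
    kcap = min(kmax, max(1, int(n_eff // 3)))
    rng = np.random.default_rng(seed)
    best: Optional[GMMFit] = None
    for k in range(1, kcap + 1):
        fit = _best_em(x, w, k, rng, n_init)
        if best is None or fit.bic > best.bic:
            best = fit
    return best


def _best_em(x, w, k, rng, n_init, max_iter: int = EM_MAX_ITER) -> GMMFit:
    """Best of one deterministic and n_init-1 jittered EM initialisations."""
    best = None
    for i in range(max(1, n_init)):
        seed = int(rng.integers(2**31 - 1))
        if i == 0:
            fit = em_fit(x, w, k=k, seed=seed, max_iter=max_iter)
        else:
            init = _init_params(x, w, k, rng)
            fit = em_fit(x, w, k=k, init=init, seed=seed, max_iter=max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def sample_from_fit(fit: GMMFit, n: int, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(fit.k, size=n, p=fit.proportions)
    return rng.normal(fit.means[comp], fit.sds[comp])


def select_k_bootstrap(
    samples,
    kmax: int = 9,
    B: int = 1000,
    alpha: float = 0.01,
    seed: Optional[int] = None,
    n_init: int = 2,
) -> int:
    """Sequential parametric-bootstrap LRT choice of the component count.

    Starting at k = 1: simulate B datasets from the fitted k-component
    model, compute the k vs k+1 likelihood-ratio statistic on each, and
    take p as the fraction of bootstrap statistics >= the observed one;
    stop and return k at the first p > alpha, else continue up to kmax.

    The replicate loop stops early once the exceedance count already
    guarantees p > alpha (the count can only grow), which leaves the
    accept/reject decision exactly as if all B replicates had run.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    x = np.asarray(samples, dtype=float)
    n = x.size
    rng = np.random.default_rng(seed)
    w = np.ones_like(x)
    boot_iter = 500  # EM iteration cap inside the bootstrap loop
    for k in range(1, kmax):
        fit_k = _best_em(x, w, k, rng, n_init)
        fit_k1 = _best_em(x, w, k + 1, rng, n_init)
        obs = max(0.0, 2.0 * (fit_k1.loglik - fit_k.loglik))
        exceed = 0
        accept = False
        for _ in range(B):
            xb = sample_from_fit(fit_k, n, rng)
            wb = np.ones_like(xb)
            fb_k = _best_em(xb, wb, k, rng, 1, max_iter=boot_iter)
            fb_k1 = _best_em(xb, wb, k + 1, rng, 1, max_iter=boot_iter)
            lrt = max(0.0, 2.0 * (fb_k1.loglik - fb_k.loglik))
            if lrt >= obs:
                exceed += 1
                if exceed > alpha * B:  # p > alpha already certain
                    accept = True
                    break
        if accept or exceed / B > alpha:
            return k
    return kmax


def peak_confidence_intervals(
    fit: GMMFit,
    samples,
    weights=None,
    B: int = 500,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> PeakSet:
    """Parametric-bootstrap percentile CIs around each component mean.

    Replicates are drawn from the fitted mixture at the effective sample
    size and refitted with k fixed (initialised at the fitted parameters);
    components are matched across replicates by sorted means.  Replicates
    whose refit collapses are discarded and counted.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    rng = np.random.default_rng(seed)
    n = int(round(fit.n_eff))
    boot_means: List[np.ndarray] = []
    discarded = 0
    for _ in range(B):
        xb = sample_from_fit(fit, n, rng)
        try:
            fb = em_fit(xb, None, k=fit.k,
                        init=(fit.proportions, fit.means, fit.sds),
                        seed=int(rng.integers(2**31 - 1)))
        except ValueError:
            discarded += 1
            continue
        if not fb.converged:
            discarded += 1
            continue
        boot_means.append(fb.means)  # GMMFit sorts by mean
    if not boot_means:
        raise RuntimeError("all bootstrap replicates failed")
    M = np.vstack(boot_means)
    a = (1.0 - level) / 2.0
    lo = np.quantile(M, a, axis=0)
    hi = np.quantile(M, 1.0 - a, axis=0)
    lo = np.minimum(lo, fit.means)
    hi = np.maximum(hi, fit.means)
    return PeakSet(fit.means.copy(), lo, hi, fit.proportions.copy(), discarded)


def mixture_density(fit: GMMFit, grid) -> np.ndarray:
    """Fitted mixture density evaluated on ``grid`` (for plotting tables)."""
    g = np.asarray(grid, dtype=float)
    logp = _log_normal_pdf(g, fit.means, fit.sds) + np.log(fit.proportions[None, :])
    m = logp.max(axis=1)
    return np.exp(m) * np.exp(logp - m[:, None]).sum(axis=1)
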
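"""Gain–death (GD) models of gene-family size evolution on a species tree.

The family size along each branch follows an immigration–death process:
new copies arrive at a per-family gain rate ``gamma`` (independent of the
current count) and each existing copy dies at rate ``delta``, both per Myr.
Over a branch of duration t this gives the closed-form transition

    X(t) | X(0)=i  =  Binomial(i, e^{-delta t})  +  Poisson(mu(t)),
    mu(t) = (gamma/delta) * (1 - e^{-delta t}),

i.e. survivors of the starting copies plus independently accumulated gains.
Likelihoods on a tree are computed by Felsenstein pruning over a truncated
state space 0..max_count, with the root marginalised under a configurable
prior (stationary Poisson(gamma/delta) by default).

Three branch-rate hypotheses are supported, mirroring the usual gain/death
model comparison: ``global`` (one rate pair for the whole tree), ``free``
(a rate pair per branch) and ``branch`` (foreground terminal branch vs the
rest).  Fits are multi-start bounded ML in log-rate space; models are
compared by AIC evidence ratios with a 2.7 cutoff (ΔAIC ≈ 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .core_io import FamilyCounts, SpeciesTree, Tree, TreeNode

__all__ = [
    "TurnoverRates",
    "TurnoverFit",
    "ModelSelection",
    "transition_prob",
    "transition_matrix",
    "family_loglik",
    "fit_turnover",
    "compare_models",
    "classify_family",
    "ancestral_marginals",
]

LOG_RATE_LO = math.log(1e-8)
LOG_RATE_HI = math.log(10.0)
RESTART_LO, RESTART_HI = 1e-5, 1.0  # restart draw window (per Myr)
EVIDENCE_RATIO_CUTOFF = 2.7


@dataclass
class TurnoverRates:
    """Per-branch-class (gamma, delta) rate pairs, per Myr."""

    rates: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        for cls, (g, d) in self.rates.items():
            if not (g >= 0 and math.isfinite(g)):
                raise ValueError(f"gain rate for {cls!r} must be finite and >= 0")
            if not (d > 0 and math.isfinite(d)):
                raise ValueError(f"death rate for {cls!r} must be finite and > 0")

    def __getitem__(self, cls: str) -> Tuple[float, float]:
        return self.rates[cls]


@dataclass
class TurnoverFit:
    model: str
    rates: TurnoverRates
    loglik: float
    n_params: int
    aic: float
    family_logliks: np.ndarray
    converged: bool
    n_restarts: int
    max_count: int
    foreground: Optional[str] = None

    def __post_init__(self):
        expected = 2.0 * self.n_params - 2.0 * self.loglik
        if abs(self.aic - expected) > 1e-6 * max(1.0, abs(expected)):
            raise ValueError("AIC inconsistent with n_params and lnL")


@dataclass
class ModelSelection:
    best: TurnoverFit
    second: Optional[TurnoverFit]
    evidence_ratio: float
    significant: bool


# ---------------------------------------------------------------------------
# transition law
# ---------------------------------------------------------------------------

def transition_prob(i: int, j: int, t: float, gamma: float, delta: float) -> float:
    """P(X(t)=j | X(0)=i) under the immigration–death law."""
    if i < 0 or j < 0:
        raise ValueError("counts must be non-negative")
    if t < 0:
        raise ValueError("time must be non-negative")
    if gamma < 0 or delta <= 0:
        raise ValueError("need gamma >= 0 and delta > 0")
    p = math.exp(-delta * t)
    mu = (gamma / delta) * (1.0 - p)
    total = 0.0
    for s in range(min(i, j) + 1):
        # Binomial(i, p) at s, in logs for stability
        if p >= 1.0:
            logb = 0.0 if s == i else -math.inf
        else:
            logb = gammaln(i + 1) - gammaln(s + 1) - gammaln(i - s + 1)
            if s > 0:
                logb += s * _safe_log(p)
            if i - s > 0:
                logb += (i - s) * _safe_log(1.0 - p)
        k = j - s
        if mu > 0:
            logpois = -mu + (k * math.log(mu) if k else 0.0) - gammaln(k + 1)
        else:
            logpois = 0.0 if k == 0 else -math.inf
        term = logb + logpois
        if term > -math.inf:
            total += math.exp(term)
    return min(total, 1.0)


def _safe_log(x: float) -> float:
    return math.log(x) if x > 0 else -math.inf


def transition_matrix(gamma: float, delta: float, t: np.ndarray, cap: int) -> np.ndarray:
    """Stack of (cap+1)x(cap+1) transition matrices, one per time in ``t``.

    Vectorised: Binomial survivor part contracted against a Toeplitz
    Poisson-gain part.  Rows sum to < 1 only by truncation at ``cap``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    S = cap + 1
    p = np.exp(-delta * t)  # (T,)
    mu = (gamma / delta) * (1.0 - p)

    idx = np.arange(S)
    # log Binomial(i, p) pmf at s, shape (T, i, s)
    i = idx[None, :, None]
    s = idx[None, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        logc = gammaln(i + 1) - gammaln(s + 1) - gammaln(i - s + 1)
        logp = np.log(p)[:, None, None]
        log1p = np.log1p(-p)[:, None, None]
        logb = logc + s * logp + np.where(i - s > 0, (i - s) * log1p, 0.0)
        # handle p == 1 (t == 0): Binomial degenerate at s = i
        logb = np.where(s > i, -np.inf, logb)
        deg = p[:, None, None] >= 1.0
        logb = np.where(deg, np.where(s == i, 0.0, -np.inf), logb)
        B = np.exp(logb)

        # Poisson(mu) pmf over 0..cap, shape (T, k)
        k = idx[None, :]
        logpois = -mu[:, None] + k * np.log(np.maximum(mu[:, None], 1e-300)) - gammaln(k + 1)
        pois = np.exp(logpois)
        zero_mu = mu <= 0
        if zero_mu.any():
            pois[zero_mu] = 0.0
            pois[zero_mu, 0] = 1.0

    # Toeplitz: T2[t, s, j] = pois[t, j-s] for j >= s
    diff = idx[None, :] - idx[:, None]  # (s, j)
    mask = diff >= 0
    T2 = np.where(mask[None, :, :], pois[:, np.clip(diff, 0, cap)], 0.0)
    return B @ T2


# ---------------------------------------------------------------------------
# tree indexing and pruning
# ---------------------------------------------------------------------------

class _TreeIndex:
    """Postorder arrays for fast repeated pruning over one tree."""

    def __init__(self, tree: Tree):
        self.tree = tree
        self.nodes: List[TreeNode] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.array(
            [self.index[id(n.parent)] if n.parent is not None else -1 for n in self.nodes]
        )
        self.lengths = np.array(
            [n.length if (n.parent is not None and n.length is not None) else 0.0 for n in self.nodes]
        )
        self.classes = [
            (n.branch_class or "background") if n.parent is not None else None
            for n in self.nodes
        ]
        self.leaf_idx = {n.name: i for i, n in enumerate(self.nodes) if n.is_leaf}
        self.root = len(self.nodes) - 1

    def class_names(self) -> List[str]:
        seen = []
        for c in self.classes:
            if c is not None and c not in seen:
                seen.append(c)
        return seen


def _branch_matrices(
    ti: _TreeIndex,
    rates: TurnoverRates,
    cap: int,
    cache: Optional[Dict] = None,
) -> List[Optional[np.ndarray]]:
    """Transition matrix for each non-root node, grouped by branch class.

    ``cache`` (keyed by branch class and rate pair) short-circuits rebuilds
    during finite-difference gradients, where only one class moves.
    """
    mats: List[Optional[np.ndarray]] = [None] * len(ti.nodes)
    for cls in ti.class_names():
        gamma, delta = rates[cls]
        key = (cls, gamma, delta)
        got = cache.get(key) if cache is not None else None
        if got is None:
            which = [i for i, c in enumerate(ti.classes) if c == cls]
            P = transition_matrix(gamma, delta, ti.lengths[which], cap)
            got = (which, P)
            if cache is not None:
                if len(cache) > 256:
                    cache.clear()
                cache[key] = got
        which, P = got
        for pos, i in enumerate(which):
            mats[i] = P[pos]
    return mats


def root_prior_vector(prior, rates: TurnoverRates, cap: int, root_class: str = "background") -> np.ndarray:
    """Distribution over root states 0..cap.

    ``prior`` is "stationary" (truncated Poisson(gamma/delta), the default),
    "uniform", or ("fixed", n).
    """
    S = cap + 1
    if prior == "stationary":
        if root_class in rates.rates:
            gamma, delta = rates[root_class]
        else:  # free model: use the average over branch classes
            gs = [g for g, _ in rates.rates.values()]
            ds = [d for _, d in rates.rates.values()]
            gamma, delta = float(np.mean(gs)), float(np.mean(ds))
        lam = gamma / delta
        k = np.arange(S)
        with np.errstate(divide="ignore"):
            logp = -lam + k * np.log(max(lam, 1e-300)) - gammaln(k + 1)
        if lam <= 0:
            vec = np.zeros(S)
            vec[0] = 1.0
            return vec
        vec = np.exp(logp - logp.max())  # normalised below; robust to underflow
        return vec / vec.sum()
    if prior == "uniform":
        return np.full(S, 1.0 / S)
    if isinstance(prior, tuple) and prior[0] == "fixed":
        vec = np.zeros(S)
        vec[int(prior[1])] = 1.0
        return vec
    raise ValueError(f"unknown root prior {prior!r}")


def family_loglik(
    tree: Tree,
    leaf_counts,
    rates: TurnoverRates,
    max_count: Optional[int] = None,
    root_prior="stationary",
) -> np.ndarray:
    """Log-likelihood of one or more families' leaf counts under ``rates``.

    ``leaf_counts`` is a mapping species -> count (one family), or a
    FamilyCounts (many families, pruned jointly).  Returns an array of
    per-family log-likelihoods.
    """
    if isinstance(leaf_counts, FamilyCounts):
        leaf_counts.check_against_tree(tree)
        species = leaf_counts.species
        counts = leaf_counts.counts
    else:
        species = list(leaf_counts.keys())
        if set(species) != set(tree.leaf_names()):
            raise ValueError("species in counts do not match tree leaves")
        counts = np.array([[leaf_counts[s] for s in species]])
    ti = _TreeIndex(tree)
    cap = _effective_cap(counts, max_count)
    return _prune(ti, species, counts, rates, cap, root_prior)


def _effective_cap(counts: np.ndarray, max_count: Optional[int]) -> int:
    floor = max(10, 2 * int(counts.max(initial=0)))
    if max_count is None:
        return floor
    return max(int(max_count), floor)


def _prune(
    ti: _TreeIndex,
    species: Sequence[str],
    counts: np.ndarray,
    rates: TurnoverRates,
    cap: int,
    root_prior,
    cache: Optional[Dict] = None,
) -> np.ndarray:
    F = counts.shape[0]
    S = cap + 1
    mats = _branch_matrices(ti, rates, cap, cache)
    partial: List[Optional[np.ndarray]] = [None] * len(ti.nodes)
    logscale = np.zeros(F)
    col_of = {sp: j for j, sp in enumerate(species)}
    for i, node in enumerate(ti.nodes):
        if node.is_leaf:
            L = np.zeros((F, S))
            obs = counts[:, col_of[node.name]]
            L[np.arange(F), obs] = 1.0
        else:
            L = np.ones((F, S))
            for ch in node.children:
                ci = ti.index[id(ch)]
                # message: sum_y P[x, y] * L_child[y]
                L *= partial[ci] @ mats[ci].T
            m = L.max(axis=1)
            m[m == 0] = 1.0
            L /= m[:, None]
            logscale += np.log(m)
        partial[i] = L
    root_class = ti.classes[0] if ti.classes[0] else "background"
    # prefer the class of a branch adjacent to the root for the prior
    for ch in ti.nodes[ti.root].children:
        root_class = ch.branch_class or "background"
        break
    prior = root_prior_vector(root_prior, rates, cap, root_class)
    lik = partial[ti.root] @ prior
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _unpack(theta: np.ndarray, model: str, ti: _TreeIndex) -> TurnoverRates:
    r = np.exp(theta)
    if model == "global":
        classes = ti.class_names()
        return TurnoverRates({c: (r[0], r[1]) for c in classes})
    if model == "branch":
        return TurnoverRates(
            {"background": (r[0], r[1]), "foreground": (r[2], r[3])}
        )
    if model == "free":
        classes = ti.class_names()
        return TurnoverRates(
            {c: (r[2 * k], r[2 * k + 1]) for k, c in enumerate(classes)}
        )
    raise ValueError(f"unknown model {model!r}")


def _n_params(model: str, ti: _TreeIndex) -> int:
    if model == "global":
        return 2
    if model == "branch":
        return 4
    if model == "free":
        return 2 * sum(1 for c in ti.classes if c is not None)
    raise ValueError(model)


def fit_turnover(
    tree: Tree,
    counts: FamilyCounts,
    model: str = "global",
    foreground: Optional[str] = None,
    n_restarts: int = 5,
    seed: Optional[int] = None,
    max_count: Optional[int] = None,
    root_prior="stationary",
    allow_absent_families: bool = False,
) -> TurnoverFit:
    """Multi-start bounded ML fit of one branch-rate hypothesis.

    The best of ``n_restarts`` L-BFGS-B runs (log-uniform random starts,
    deterministic given ``seed``) is returned; total non-convergence is
    flagged on the fit, not raised.

    Families with zero genes in every species are rejected: in real data
    such families are unobservable.  Simulation studies, where the zero
    rows are genuinely observed, may keep them with
    ``allow_absent_families=True``.
    """
    if model not in ("global", "free", "branch"):
        raise ValueError(f"unknown model {model!r}")
    counts.check_against_tree(tree)
    if not allow_absent_families and (counts.counts.sum(axis=1) == 0).any():
        raise ValueError("families absent from all species are untestable; drop them first")
    # work on a copy: branch/free models relabel branch classes and must
    # never mutate the caller's tree
    work = tree
    if model == "branch":
        if foreground is None:
            raise ValueError("branch model requires a foreground species")
        work = SpeciesTree(tree.copy().root, ultrametric=False)
        work.set_foreground(foreground)
    elif model == "free":
        work = tree.copy()
    ti = _TreeIndex(work)
    if model == "free":
        # one class per branch: label each non-root node uniquely
        for i, node in enumerate(ti.nodes):
            if node.parent is not None:
                node.branch_class = f"b{i}"
        ti = _TreeIndex(work)
    cap = _effective_cap(counts.counts, max_count)
    npar = _n_params(model, ti)
    rng = np.random.default_rng(seed)
    cache: Dict = {}

    def objective(theta: np.ndarray) -> float:
        rates = _unpack(theta, model, ti)
        ll = _prune(ti, counts.species, counts.counts, rates, cap, root_prior, cache)
        val = -float(ll.sum())
        return val if math.isfinite(val) else 1e12

    lo, hi = math.log(RESTART_LO), math.log(RESTART_HI)
    best = None
    any_converged = False
    for _ in range(max(1, n_restarts)):
        x0 = rng.uniform(lo, hi, size=npar)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(LOG_RATE_LO, LOG_RATE_HI)] * npar,
            options={"maxiter": 100, "ftol": 1e-9},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    rates = _unpack(best.x, model, ti)
    fam_ll = _prune(ti, counts.species, counts.counts, rates, cap, root_prior)
    lnL = float(fam_ll.sum())
    return TurnoverFit(
        model=model,
        rates=rates,
        loglik=lnL,
        n_params=npar,
        aic=2.0 * npar - 2.0 * lnL,
        family_logliks=fam_ll,
        converged=any_converged,
        n_restarts=n_restarts,
        max_count=cap,
        foreground=foreground,
    )


def compare_models(fits: Sequence[TurnoverFit]) -> ModelSelection:
    """AIC model selection with the evidence-ratio 2.7 significance rule.

    evidence ratio = exp((AIC_second - AIC_best)/2); ties broken toward
    fewer parameters.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ranked = sorted(fits, key=lambda f: (f.aic, f.n_params))
    best, second = ranked[0], ranked[1]
    ratio = math.exp((second.aic - best.aic) / 2.0)
    return ModelSelection(
        best=best,
        second=second,
        evidence_ratio=ratio,
        significant=ratio >= EVIDENCE_RATIO_CUTOFF,
    )


# ---------------------------------------------------------------------------
# ancestral reconstruction and family classification
# ---------------------------------------------------------------------------

def ancestral_marginals(
    tree: Tree,
    leaf_counts: Dict[str, int],
    rates: TurnoverRates,
    max_count: Optional[int] = None,
    root_prior="stationary",
) -> Dict[TreeNode, np.ndarray]:
    """Marginal posterior over each node's count given the leaf counts.

    Upward pruning pass plus a downward pass; posterior at node v is
    proportional to (below-v likelihood) x (rest-of-tree likelihood).
    """
    ti = _TreeIndex(tree)
    species = list(leaf_counts.keys())
    counts = np.array([[leaf_counts[s] for s in species]])
    cap = _effective_cap(counts, max_count)
    S = cap + 1
    mats = _branch_matrices(ti, rates, cap)

    col_of = {sp: 0 for sp in species}
    below: List[Optional[np.ndarray]] = [None] * len(ti.nodes)
    for i, node in enumerate(ti.nodes):
        if node.is_leaf:
            v = np.zeros(S)
            v[leaf_counts[node.name]] = 1.0
        else:
            v = np.ones(S)
            for ch in node.children:
                ci = ti.index[id(ch)]
                v = v * (mats[ci] @ below[ci])
            s = v.max()
            if s > 0:
                v = v / s
        below[i] = v

    root_class = "background"
    for ch in ti.nodes[ti.root].children:
        root_class = ch.branch_class or "background"
        break
    prior = root_prior_vector(root_prior, rates, cap, root_class)

    above: List[Optional[np.ndarray]] = [None] * len(ti.nodes)
    above[ti.root] = prior
    for i in range(len(ti.nodes) - 1, -1, -1):
        node = ti.nodes[i]
        for ch in node.children:
            ci = ti.index[id(ch)]
            msg = above[i].copy()
            for sib in node.children:
                if sib is ch:
                    continue
                si = ti.index[id(sib)]
                msg = msg * (mats[si] @ below[si])
            # pass through the child's own branch: sum_x msg[x] P[x, y]
            v = msg @ mats[ci]
            s = v.max()
            if s > 0:
                v = v / s
            above[ci] = v

    out: Dict[TreeNode, np.ndarray] = {}
    for i, node in enumerate(ti.nodes):
        post = below[i] * above[i]
        tot = post.sum()
        out[node] = post / tot if tot > 0 else post
    return out


def classify_family(
    branch_fit: TurnoverFit,
    tree: Tree,
    leaf_counts: Dict[str, int],
    max_count: Optional[int] = None,
    root_prior="stationary",
) -> Tuple[str, bool]:
    """Call a family expanded/contracted/stable on the foreground branch.

    The ML (posterior-mode) ancestral count at the foreground branch's
    parent node is compared with the observed foreground leaf count;
    ``lost_all`` is set when the foreground count is 0 but the ancestor
    had at least one copy.
    """
    fg = branch_fit.foreground
    if fg is None:
        raise ValueError("branch fit carries no foreground species")
    work = SpeciesTree(tree.copy().root, ultrametric=False)
    work.set_foreground(fg)
    marg = ancestral_marginals(work, leaf_counts, branch_fit.rates, max_count, root_prior)
    fg_leaf = next(l for l in work.leaves() if l.name == fg)
    parent_post = marg[fg_leaf.parent]
    recon = int(np.argmax(parent_post))
    obs = leaf_counts[fg]
    lost_all = obs == 0 and recon > 0
    if obs > recon:
        return "expanded", lost_all
    if obs < recon:
        return "contracted", lost_all
    return "stable", lost_all
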
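"""Pairwise synonymous-substitution (Ks) estimation from codon alignments.

Two routes are provided:

* ``gy94_fit`` — maximum likelihood under a Goldman–Yang-type codon model
  with F3x4 stationary frequencies.  The generator over the 61 sense codons
  has entries proportional to pi_j, kappa*pi_j, omega*pi_j or
  kappa*omega*pi_j depending on whether the single-nucleotide change is a
  transition and/or nonsynonymous; multi-nucleotide changes are forbidden.
  The generator is scaled so branch length t is in expected substitutions
  per codon.  dS is t * rho_S / (3 * f_S), where rho_S is the synonymous
  fraction of substitution flux under the fitted model and f_S the
  synonymous site fraction of the same model with omega fixed to 1
  (mutational site counting).
* ``ng86_ks`` — Nei–Gojobori (1986) counting with Jukes–Cantor correction,
  used as a fast cross-check.  Changes to stop codons are excluded from
  site counts and pathways through stops are discarded.

Codon columns containing a gap or ambiguity in either sequence are dropped
before counting or likelihood evaluation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio.Data import CodonTable
from scipy.optimize import minimize

__all__ = [
    "CodonPair",
    "KsEstimate",
    "CODONS",
    "CODON_INDEX",
    "f3x4_freqs",
    "build_generator",
    "transition_matrix_codon",
    "flux_fractions",
    "gy94_fit",
    "ng86_ks",
]

NUCS = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]  # universal code
STOP_CODONS = set(_TABLE.stop_codons)
CODONS: List[str] = [
    a + b + c
    for a in NUCS
    for b in NUCS
    for c in NUCS
    if a + b + c not in STOP_CODONS
]
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(CODONS)}
AA = [_TABLE.forward_table[c] for c in CODONS]
N_CODONS = len(CODONS)  # 61

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _pair_relations():
    """Arrays describing all single-nucleotide sense-codon pairs."""
    ii, jj, is_ts, is_syn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            is_ts.append(diffs[0] in _TRANSITIONS)
            is_syn.append(AA[i] == AA[j])
    return (
        np.array(ii),
        np.array(jj),
        np.array(is_ts, dtype=bool),
        np.array(is_syn, dtype=bool),
    )


_II, _JJ, _IS_TS, _IS_SYN = _pair_relations()


@dataclass
class CodonPair:
    """Two gap-aligned in-frame coding sequences."""

    seq1: str
    seq2: str

    def __post_init__(self):
        self.seq1 = self.seq1.upper()
        self.seq2 = self.seq2.upper()
        if len(self.seq1) != len(self.seq2):
            raise ValueError("aligned sequences differ in length")
        if len(self.seq1) % 3 != 0:
            raise ValueError("alignment length not divisible by 3")

    def codon_columns(self) -> List[Tuple[str, str]]:
        """Comparable codon columns: both codons sense, pure ACGT."""
        out = []
        for k in range(0, len(self.seq1), 3):
            c1, c2 = self.seq1[k : k + 3], self.seq2[k : k + 3]
            if c1 in CODON_INDEX and c2 in CODON_INDEX:
                out.append((c1, c2))
        return out


@dataclass
class KsEstimate:
    t: float
    kappa: float
    omega: float
    dS: Optional[float]
    dN: Optional[float]
    loglik: Optional[float]
    method: str
    n_codons: int
    saturated: bool = False
    undefined: bool = False


# ---------------------------------------------------------------------------
# F3x4 frequencies and the GY generator
# ---------------------------------------------------------------------------

def f3x4_freqs(pair: CodonPair, pseudocount: float = 0.5 / N_CODONS) -> np.ndarray:
    """F3x4 sense-codon frequencies from both sequences of the pair.

    Position-specific nucleotide frequencies are tallied over ungapped
    codon columns, multiplied per codon, stop codons dropped, and the
    result renormalised; zero-frequency codons receive a small
    pseudocount so the generator stays irreducible.
    """
    cols = pair.codon_columns()
    if not cols:
        raise ValueError("no comparable codon columns")
    tallies = np.zeros((3, 4))
    for c1, c2 in cols:
        for pos in range(3):
            tallies[pos, NUCS.index(c1[pos])] += 1
            tallies[pos, NUCS.index(c2[pos])] += 1
    if (tallies.sum(axis=1) == 0).any():
        raise ValueError("a codon position has no observed nucleotides")
    posfreq = tallies / tallies.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            posfreq[0, NUCS.index(c[0])]
            * posfreq[1, NUCS.index(c[1])]
            * posfreq[2, NUCS.index(c[2])]
            for c in CODONS
        ]
    )
    if (freqs == 0).any():
        freqs = freqs + np.where(freqs == 0, pseudocount, 0.0)
    return freqs / freqs.sum()


def build_generator(freqs: np.ndarray, kappa: float, omega: float, scale: bool = True):
    """GY-type generator Q over sense codons.

    Returns (Q, total_flux_before_scaling).  With ``scale`` the generator
    is normalised so that -sum_i pi_i Q_ii == 1, i.e. time is measured in
    expected substitutions per codon.
    """
    Q = np.zeros((N_CODONS, N_CODONS))
    rate = freqs[_JJ] * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_SYN, 1.0, omega)
    Q[_II, _JJ] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    flux = float(-(freqs * np.diag(Q)).sum())
    if scale and flux > 0:
        Q = Q / flux
    return Q, flux


def flux_fractions(freqs: np.ndarray, kappa: float, omega: float) -> Tuple[float, float]:
    """(rho_S, f_S): synonymous flux fraction at (kappa, omega) and
    synonymous site fraction of the same model at omega = 1."""

    def syn_fraction(om: float) -> float:
        rate = freqs[_JJ] * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_SYN, 1.0, om)
        w = freqs[_II] * rate
        return float(w[_IS_SYN].sum() / w.sum())

    return syn_fraction(omega), syn_fraction(1.0)


def transition_matrix_codon(freqs: np.ndarray, kappa: float, omega: float, t: float) -> np.ndarray:
    """P(t) = expm(Q t) via eigendecomposition of the symmetrised generator."""
    Q, _ = build_generator(freqs, kappa, omega)
    d = np.sqrt(freqs)
    S = (Q * d[:, None]) / d[None, :]  # D^{1/2} Q D^{-1/2}
    S = 0.5 * (S + S.T)  # symmetric up to round-off by reversibility
    lam, U = np.linalg.eigh(S)
    P = (U * np.exp(lam * t)) @ U.T
    P = P * d[None, :] / d[:, None]
    np.clip(P, 0.0, None, out=P)
    return P / P.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# GY94 pairwise maximum likelihood
# ---------------------------------------------------------------------------

T_BOUNDS = (1e-4, 30.0)
KAPPA_BOUNDS = (0.1, 20.0)
OMEGA_BOUNDS = (1e-3, 5.0)


def _pair_count_matrix(pair: CodonPair) -> np.ndarray:
    C = np.zeros((N_CODONS, N_CODONS))
    for c1, c2 in pair.codon_columns():
        C[CODON_INDEX[c1], CODON_INDEX[c2]] += 1.0
    return C


def gy94_fit(
    pair: CodonPair,
    n_restarts: int = 5,
    seed: Optional[int] = None,
    min_codons: int = 30,
) -> KsEstimate:
    """Best-of-``n_restarts`` bounded ML fit of (t, kappa, omega).

    Optimisation is over the logs of the three parameters (L-BFGS-B);
    restart starting points are log-uniform within the bounds and
    deterministic given ``seed``.  A fit with t at its upper bound is
    flagged ``saturated``.
    """
    cols = pair.codon_columns()
    n = len(cols)
    if n < min_codons:
        raise ValueError(f"only {n} comparable codon columns (< {min_codons})")
    freqs = f3x4_freqs(pair)
    C = _pair_count_matrix(pair)
    n_diff = sum(1 for a, b in cols if a != b)
    if n_diff == 0:
        return KsEstimate(0.0, 1.0, 1.0, 0.0, 0.0, None, "GY-F3x4", n)

    logpi = np.log(freqs)
    d = np.sqrt(freqs)
    eig_cache: Dict[Tuple[float, float], Tuple[np.ndarray, np.ndarray]] = {}

    def eig_for(kappa: float, omega: float):
        key = (kappa, omega)
        got = eig_cache.get(key)
        if got is None:
            Q, _ = build_generator(freqs, kappa, omega)
            A = (Q * d[:, None]) / d[None, :]  # D^{1/2} Q D^{-1/2}
            S = 0.5 * (A + A.T)
            got = np.linalg.eigh(S)
            if len(eig_cache) > 64:
                eig_cache.clear()
            eig_cache[key] = got
        return got

    def negloglik(theta: np.ndarray) -> float:
        t, kappa, omega = np.exp(theta)
        lam, U = eig_for(kappa, omega)
        P = (U * np.exp(lam * t)) @ U.T
        P = P * d[None, :] / d[:, None]
        np.clip(P, 1e-300, None, out=P)
        ll = float((C * (logpi[:, None] + np.log(P))).sum())
        return -ll if math.isfinite(ll) else 1e12

    bounds = [
        (math.log(T_BOUNDS[0]), math.log(T_BOUNDS[1])),
        (math.log(KAPPA_BOUNDS[0]), math.log(KAPPA_BOUNDS[1])),
        (math.log(OMEGA_BOUNDS[0]), math.log(OMEGA_BOUNDS[1])),
    ]
    rng = np.random.default_rng(seed)
    best = None
    for r in range(max(1, n_restarts)):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        res = minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    t, kappa, omega = (float(v) for v in np.exp(best.x))
    rho_s, f_s = flux_fractions(freqs, kappa, omega)
    dS = t * rho_s / (3.0 * f_s)
    dN = t * (1.0 - rho_s) / (3.0 * (1.0 - f_s))
    saturated = t >= T_BOUNDS[1] * 0.999
    return KsEstimate(
        t=t,
        kappa=kappa,
        omega=omega,
        dS=dS,
        dN=dN,
        loglik=-float(best.fun),
        method="GY-F3x4",
        n_codons=n,
        saturated=saturated,
    )


# ---------------------------------------------------------------------------
# NG86 counting estimator
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> Tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    At each position the three single-nucleotide changes are classified;
    changes producing a stop codon are excluded, and the position
    contributes the synonymous fraction of the remaining viable changes.
    """
    aa = _TABLE.forward_table[codon]
    s_sites = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            n_valid += 1
            if _TABLE.forward_table[mut] == aa:
                n_syn += 1
        if n_valid:
            s_sites += n_syn / n_valid
    return s_sites, 3.0 - s_sites


_SITE_CACHE = {c: _codon_site_counts(c) for c in CODONS}


def _pathway_differences(c1: str, c2: str) -> Tuple[float, float]:
    """Average (syn, nonsyn) difference counts over all mutational
    pathways between two codons, skipping pathways through stops."""
    if c1 == c2:
        return 0.0, 0.0
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]
    syn_tot = non_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _TABLE.forward_table[cur] == _TABLE.forward_table[nxt]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            syn_tot += syn
            non_tot += non
            n_paths += 1
    if n_paths == 0:
        # no stop-free pathway: fall back to classifying each position change
        # directly against the end codon (rare; keeps the pair usable)
        syn = sum(
            1
            for pos in diff_pos
            if _TABLE.forward_table[c1] == _TABLE.forward_table[c2]
        )
        return float(syn), float(len(diff_pos) - syn)
    return syn_tot / n_paths, non_tot / n_paths


def _jukes_cantor(p: float) -> Optional[float]:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_ks(pair: CodonPair, min_codons: int = 30) -> KsEstimate:
    """Nei–Gojobori (1986) dS/dN with Jukes–Cantor correction."""
    cols = pair.codon_columns()
    n = len(cols)
    if n < min_codons:
        raise ValueError(f"only {n} comparable codon columns (< {min_codons})")
    S1 = sum(_SITE_CACHE[c1][0] for c1, _ in cols)
    S2 = sum(_SITE_CACHE[c2][0] for _, c2 in cols)
    S = 0.5 * (S1 + S2)
    N = 3.0 * n - S
    Sd = Nd = 0.0
    for c1, c2 in cols:
        sd, nd = _pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    return KsEstimate(
        t=float("nan"),
        kappa=float("nan"),
        omega=float("nan"),
        dS=dS,
        dN=dN,
        loglik=None,
        method="NG86",
        n_codons=n,
        undefined=dS is None,
    )
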
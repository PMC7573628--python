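"""Independent reference implementations used only by the tests.

Each oracle is deliberately written as plain, loop-based code that shares
no machinery with the package: truncated-generator matrix exponentials for
the gain–death transition law, exhaustive ancestral-state enumeration for
the tree likelihood, a single-file NG86 calculator, a from-scratch
recursive clade splitter, and exact-rational Fisher enumeration.
"""

from fractions import Fraction
from itertools import permutations
from math import comb, exp, log

import numpy as np
import scipy.linalg


# ---------------------------------------------------------------------------
# gain–death transition probability via truncated generator expm
# ---------------------------------------------------------------------------

def expm_transition(i, j, t, gamma, delta, cap=60):
    Q = np.zeros((cap + 1, cap + 1))
    for n in range(cap + 1):
        if n < cap:
            Q[n, n + 1] = gamma
        if n > 0:
            Q[n, n - 1] = n * delta
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return scipy.linalg.expm(Q * t)[i, j]


# ---------------------------------------------------------------------------
# exhaustive tree likelihood on a 3-leaf rooted tree ((A,B),C)
# ---------------------------------------------------------------------------

def enumerate_loglik_3leaf(branch_lengths, counts, gamma, delta, prior, cap, trans):
    """Sum over all (root, internal) state pairs.

    ``branch_lengths`` = (t_AB_parent, t_A, t_B, t_C); ``trans`` is the
    transition function under test's *law* supplied externally so this
    stays a pure enumeration; ``prior`` maps state -> probability.
    """
    t_anc, t_a, t_b, t_c = branch_lengths
    ca, cb, cc = counts
    total = 0.0
    for root in range(cap + 1):
        pr = prior[root]
        if pr == 0:
            continue
        for anc in range(cap + 1):
            total += (
                pr
                * trans(root, anc, t_anc, gamma, delta)
                * trans(anc, ca, t_a, gamma, delta)
                * trans(anc, cb, t_b, gamma, delta)
                * trans(root, cc, t_c, gamma, delta)
            )
    return log(total)


# ---------------------------------------------------------------------------
# single-file NG86
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODE = {
    a + b + c: _AAS[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def _ng86_sites(codon):
    aa = _CODE[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _CODE[alt] == "*":
                continue
            valid += 1
            if _CODE[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s


def _ng86_diffs(c1, c2):
    pos = [k for k in range(3) if c1[k] != c2[k]]
    if not pos:
        return 0.0, 0.0
    sd = nd = 0.0
    paths = 0
    for order in permutations(pos):
        cur = c1
        s = n = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if _CODE[nxt] == "*":
                blocked = True
                break
            if _CODE[nxt] == _CODE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if not blocked:
            sd += s
            nd += n
            paths += 1
    if paths == 0:
        if _CODE[c1] == _CODE[c2]:
            return float(len(pos)), 0.0
        return 0.0, float(len(pos))
    return sd / paths, nd / paths


def ng86_oracle(seq1, seq2):
    """Returns (dS, dN); None where the JC correction is undefined."""
    cods = []
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k : k + 3].upper(), seq2[k : k + 3].upper()
        if set(c1) <= set("ACGT") and set(c2) <= set("ACGT") \
                and _CODE[c1] != "*" and _CODE[c2] != "*":
            cods.append((c1, c2))
    S = 0.5 * (sum(_ng86_sites(a) for a, _ in cods) + sum(_ng86_sites(b) for _, b in cods))
    N = 3.0 * len(cods) - S
    Sd = Nd = 0.0
    for a, b in cods:
        s, n = _ng86_diffs(a, b)
        Sd += s
        Nd += n
    out = []
    for diff, sites in ((Sd, S), (Nd, N)):
        p = diff / sites if sites > 0 else 0.0
        out.append(None if p >= 0.75 else -0.75 * log(1 - 4 * p / 3))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# recursive clade splitting, from scratch over leaf-name sets
# ---------------------------------------------------------------------------

def split_oracle(node, ks_lookup, threshold):
    """Returns the list of retained subclades as frozensets of leaf names.

    ``node`` is a (left, right) nested-tuple topology with leaf names at
    the tips; every pair is re-checked at every level.
    """

    def leaves(n):
        if isinstance(n, str):
            return [n]
        return leaves(n[0]) + leaves(n[1])

    def ok(names):
        for x in range(len(names)):
            for y in range(x + 1, len(names)):
                v = ks_lookup(names[x], names[y])
                if v is None or v > threshold:
                    return False
        return True

    names = leaves(node)
    if isinstance(node, str) or ok(names):
        return [frozenset(names)]
    return split_oracle(node[0], ks_lookup, threshold) + split_oracle(
        node[1], ks_lookup, threshold
    )


# ---------------------------------------------------------------------------
# exact two-sided Fisher by full enumeration over fixed margins
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs * (1 + Fraction(1, 10**7)):
            total += p_k
    return float(total)
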
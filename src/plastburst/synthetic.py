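"""Synthetic data generators with machine-readable ground truth.

Every stage of the pipeline can be exercised without any downloads: these
generators produce inputs with the statistical structure the corresponding
stage assumes, each paired with a :class:`TruthRecord` capturing the seed,
the parameters and the per-item truth (simulated rates, true dS, planted
mixture components, planted insertion intervals, duplication-node ages).

All generators are pure functions of (parameters, seed).  A pipeline run
uses one master seed split deterministically into per-stage substreams by
hashing ``"{master}:{stage}"`` (sha256, reduced mod 2^31) so stages can be
re-run independently.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_io import FamilyCounts, SpeciesTree, Tree, TreeNode, parse_newick
from .ks_engine import CODONS, CodonPair, flux_fractions, transition_matrix_codon
from .turnover import TurnoverRates, root_prior_vector

__all__ = [
    "TruthRecord",
    "split_seed",
    "angiosperm_timetree",
    "ANGIOSPERM_11_NEWICK",
    "sim_family_counts",
    "sim_codon_pair",
    "t_for_ds",
    "sim_ks_mixture",
    "sim_family_tree_with_ks",
    "sim_nupt_genome",
]

# 11 angiosperm species (three-letter codes), topology with Amborella (Atr)
# sister to all other angiosperms and the magnoliid avocado (Pah) sister to
# the monocot+eudicot supergroup; ultrametric, branch lengths in Myr from
# TimeTree-style median divergence estimates.
ANGIOSPERM_11_NEWICK = (
    "(Atr:179,(Pah:168,((Osj:50,Zma:50):110,(Vvi:117,(((Lpu:28,Vsu:28):40,"
    "Fal:68):42,((Ath:93,Mob:93):9,Sbi:102):8):7):43):8):11);"
)


def angiosperm_timetree() -> SpeciesTree:
    """The 11-species ultrametric study tree (branch lengths in Myr)."""
    tree = parse_newick(ANGIOSPERM_11_NEWICK)
    return SpeciesTree(tree.root)


def split_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2^31."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**31)


@dataclass
class TruthRecord:
    generator: str
    seed: int
    params: Dict
    items: object

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# gene-family counts under the immigration–death law
# ---------------------------------------------------------------------------

def sim_family_counts(
    tree: Tree,
    rates: TurnoverRates,
    n_families: int,
    root_prior="stationary",
    seed: int = 0,
    max_root: int = 200,
) -> Tuple[FamilyCounts, TruthRecord]:
    """Evolve ``n_families`` independent families down the tree.

    The root count is drawn from the root prior; along each branch the
    count becomes Binomial(count, e^{-delta t}) survivors plus
    Poisson((gamma/delta)(1 - e^{-delta t})) gains — exactly the
    transition law the turnover likelihood assumes.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = list(tree.preorder())
    root_class = "background"
    for ch in tree.root.children:
        root_class = ch.branch_class or "background"
        break
    prior = root_prior_vector(root_prior, rates, max_root, root_class)
    state: Dict[int, np.ndarray] = {}
    state[id(tree.root)] = rng.choice(len(prior), size=n_families, p=prior)
    leaves: Dict[str, np.ndarray] = {}
    for node in nodes:
        if node is tree.root:
            pass
        else:
            gamma, delta = rates[node.branch_class or "background"]
            t = node.length or 0.0
            p = math.exp(-delta * t)
            mu = (gamma / delta) * (1.0 - p)
            parent_counts = state[id(node.parent)]
            survivors = rng.binomial(parent_counts, p)
            gains = rng.poisson(mu, size=n_families)
            state[id(node)] = survivors + gains
        if node.is_leaf:
            leaves[node.name] = state[id(node)]
    species = sorted(leaves)
    counts = np.column_stack([leaves[s] for s in species])
    fam_ids = [f"fam{i:05d}" for i in range(n_families)]
    truth = TruthRecord(
        generator="sim_family_counts",
        seed=seed,
        params={
            "rates": {c: list(v) for c, v in rates.rates.items()},
            "n_families": n_families,
            "root_prior": str(root_prior),
        },
        items={"species": species},
    )
    return FamilyCounts(fam_ids, species, counts), truth


# ---------------------------------------------------------------------------
# codon pairs under the GY generator
# ---------------------------------------------------------------------------

def t_for_ds(ds: float, kappa: float, omega: float, freqs: np.ndarray) -> float:
    """Branch length (subs/codon) whose model dS equals ``ds``."""
    rho_s, f_s = flux_fractions(freqs, kappa, omega)
    return ds * 3.0 * f_s / rho_s


def sim_codon_pair(
    n_codons: int,
    t: float,
    kappa: float,
    omega: float,
    codon_freqs: Optional[np.ndarray] = None,
    seed: int = 0,
) -> Tuple[CodonPair, TruthRecord]:
    """Two sequences diverged for total time ``t`` from a common ancestor.

    The ancestor is drawn from the stationary frequencies and each
    descendant evolves independently for t/2 under the GY generator.
    The truth records the model dS/dN implied by the generator's own
    flux decomposition (the same convention the estimator uses).
    """
    if codon_freqs is None:
        freqs = np.full(len(CODONS), 1.0 / len(CODONS))
    else:
        freqs = np.asarray(codon_freqs, dtype=float)
        freqs = freqs / freqs.sum()
    rng = np.random.default_rng(seed)
    P_half = transition_matrix_codon(freqs, kappa, omega, t / 2.0)
    anc = rng.choice(len(CODONS), size=n_codons, p=freqs)
    seqs = []
    for _ in range(2):
        child = np.array([rng.choice(len(CODONS), p=P_half[a]) for a in anc])
        seqs.append("".join(CODONS[c] for c in child))
    rho_s, f_s = flux_fractions(freqs, kappa, omega)
    truth = TruthRecord(
        generator="sim_codon_pair",
        seed=seed,
        params={"n_codons": n_codons, "t": t, "kappa": kappa, "omega": omega},
        items={
            "true_dS": t * rho_s / (3.0 * f_s),
            "true_dN": t * (1.0 - rho_s) / (3.0 * (1.0 - f_s)),
            "rho_S": rho_s,
            "f_S": f_s,
        },
    )
    return CodonPair(seqs[0], seqs[1]), truth


# ---------------------------------------------------------------------------
# Ks mixtures
# ---------------------------------------------------------------------------

def sim_ks_mixture(
    components: Sequence[Tuple[float, float, float]],
    n: int,
    window: Tuple[float, float] = (0.05, 5.0),
    seed: int = 0,
) -> Tuple[np.ndarray, TruthRecord]:
    """Draw ``n`` values from a (lambda, mu, sigma) mixture, rejecting
    draws outside ``window``; the acceptance rate is recorded."""
    lam = np.array([c[0] for c in components], dtype=float)
    if abs(lam.sum() - 1.0) > 1e-9:
        raise ValueError("mixing proportions must sum to 1")
    mu = np.array([c[1] for c in components], dtype=float)
    sd = np.array([c[2] for c in components], dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    proposed = 0
    lo, hi = window
    while out.size < n:
        m = max(2 * (n - out.size), 100)
        comp = rng.choice(len(components), size=m, p=lam)
        draw = rng.normal(mu[comp], sd[comp])
        proposed += m
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    samples = out[:n]
    truth = TruthRecord(
        generator="sim_ks_mixture",
        seed=seed,
        params={"components": [list(c) for c in components], "n": n, "window": list(window)},
        items={"acceptance_rate": n / proposed if proposed else 1.0},
    )
    return samples, truth


# ---------------------------------------------------------------------------
# duplication trees with planted node ages
# ---------------------------------------------------------------------------

def sim_family_tree_with_ks(
    n_leaves: int,
    node_ages: Optional[Sequence[float]] = None,
    ks_noise_sd: float = 0.05,
    seed: int = 0,
) -> Tuple[Tree, Dict[Tuple[str, str], float], TruthRecord]:
    """Random coalescent-style binary gene tree plus a pairwise Ks matrix.

    Clades are merged in random pairs at increasing node ages (supplied,
    or cumulative exponential increments); Ks between two leaves is twice
    the age of their spanning node plus Gaussian noise, floored at zero.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    if node_ages is None:
        ages = np.cumsum(rng.exponential(0.4, size=n_leaves - 1))
    else:
        ages = np.sort(np.asarray(node_ages, dtype=float))
        if len(ages) != n_leaves - 1:
            raise ValueError("need n_leaves - 1 node ages")
    clades: List[Tuple[TreeNode, float]] = [
        (TreeNode(name=f"g{i}", length=None), 0.0) for i in range(n_leaves)
    ]
    age_of: Dict[frozenset, float] = {}
    leafsets: Dict[int, frozenset] = {id(c[0]): frozenset([c[0].name]) for c in clades}
    for age in ages:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        (a, age_a), (b, age_b) = clades[i], clades[j]
        a.length = age - age_a
        b.length = age - age_b
        parent = TreeNode(length=None)
        parent.add(a)
        parent.add(b)
        merged = leafsets[id(a)] | leafsets[id(b)]
        leafsets[id(parent)] = merged
        age_of[merged] = float(age)
        clades = [c for k, c in enumerate(clades) if k not in (i, j)]
        clades.append((parent, float(age)))
    tree = Tree(clades[0][0])

    # spanning-node age per leaf pair
    names = tree.leaf_names()
    ks: Dict[Tuple[str, str], float] = {}
    pair_age: Dict[Tuple[str, str], float] = {}
    # MRCA age per pair = age of the smallest stored clade containing both
    sets_by_size = sorted(age_of.items(), key=lambda kv: len(kv[0]))
    for ia in range(len(names)):
        for ib in range(ia + 1, len(names)):
            a, b = names[ia], names[ib]
            for s, node_age in sets_by_size:
                if a in s and b in s:
                    pair_age[(a, b)] = node_age
                    break
    for (a, b), age in pair_age.items():
        noise = rng.normal(0.0, ks_noise_sd) if ks_noise_sd > 0 else 0.0
        ks[(a, b)] = max(0.0, 2.0 * age + noise)
    truth = TruthRecord(
        generator="sim_family_tree_with_ks",
        seed=seed,
        params={"n_leaves": n_leaves, "ks_noise_sd": ks_noise_sd},
        items={"node_ages": ages.tolist()},
    )
    return tree, ks, truth


# ---------------------------------------------------------------------------
# nuclear genome with planted plastid insertions
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    if divergence <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    subs = {
        "A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG",
    }
    for i in np.nonzero(hit)[0]:
        arr[i] = subs[arr[i]][rng.integers(0, 3)]
    return "".join(arr)


def sim_nupt_genome(
    genome_bp: int = 2_000_000,
    plastid_bp: int = 160_000,
    n_insertions: int = 300,
    size_lognorm: Tuple[float, float] = (math.log(200.0), 1.2),
    divergence: Tuple[float, float] = (0.0, 0.10),
    seed: int = 0,
    target_fraction: Optional[float] = None,
) -> Tuple[str, str, List[Tuple[int, int, float]], TruthRecord]:
    """Random nuclear sequence with planted, partially diverged plastid
    fragments at non-overlapping positions.

    Insertion sizes are lognormal (right-skewed unimodal); per-insertion
    divergence is uniform in ``divergence``.  With ``target_fraction``
    set, sizes are drawn until the planted total reaches that fraction of
    ``genome_bp`` (the insertion count then varies).  Returns
    (nuclear sequence, plastid sequence, truth intervals, TruthRecord);
    truth intervals are 0-based half-open (start, end, divergence).
    """
    rng = np.random.default_rng(seed)
    plastid = _random_seq(rng, plastid_bp)
    mu, sigma = size_lognorm

    sizes: List[int] = []
    if target_fraction is not None:
        want = int(target_fraction * genome_bp)
        total = 0
        while total < want:
            s = int(np.clip(rng.lognormal(mu, sigma), 34, plastid_bp // 2))
            if total + s > want + 500:
                s = want - total
                if s < 34:
                    break
            sizes.append(s)
            total += s
    else:
        sizes = [
            int(np.clip(rng.lognormal(mu, sigma), 34, plastid_bp // 2))
            for _ in range(n_insertions)
        ]
    if sum(sizes) > 0.8 * genome_bp:
        raise ValueError("requested insertions exceed 80% of the genome")

    nuclear = list(_random_seq(rng, genome_bp))
    placed: List[Tuple[int, int, float]] = []
    occupied: List[Tuple[int, int]] = []
    for s in sizes:
        for _attempt in range(200):
            start = int(rng.integers(0, genome_bp - s))
            end = start + s
            if all(end <= a or start >= b for a, b in occupied):
                break
        else:
            continue
        occupied.append((start, end))
        psrc = int(rng.integers(0, plastid_bp - s))
        div = float(rng.uniform(*divergence))
        frag = _mutate(rng, plastid[psrc : psrc + s], div)
        if rng.random() < 0.5:
            from .nupt import revcomp

            frag = revcomp(frag)
        nuclear[start:end] = list(frag)
        placed.append((start, end, div))
    placed.sort()
    truth = TruthRecord(
        generator="sim_nupt_genome",
        seed=seed,
        params={
            "genome_bp": genome_bp,
            "plastid_bp": plastid_bp,
            "n_insertions": n_insertions,
            "size_lognorm": list(size_lognorm),
            "divergence": list(divergence),
            "target_fraction": target_fraction,
        },
        items={
            "intervals": [[a, b, d] for a, b, d in placed],
            "planted_bp": sum(b - a for a, b, _ in placed),
            "planted_fraction": sum(b - a for a, b, _ in placed) / genome_bp,
        },
    )
    return "".join(nuclear), plastid, placed, truth
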
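"""GO-term over/under-representation by Fisher's exact test + Bonferroni.

Each term annotating at least one gene of the universe is tested on the
2x2 table (subset with term, subset without, rest with, rest without)
with the two-sided Fisher exact test; p-values are Bonferroni-corrected
by the number of terms tested and called significant below 0.05.  The
default universe is the annotated genes only, matching the usual
"all genes present in the genome" denominator of annotation pipelines;
direction is reported from the Haldane-corrected sample odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Set

from scipy.stats import fisher_exact

__all__ = ["EnrichmentResult", "fisher_exact_2x2", "enrich_terms"]


@dataclass
class EnrichmentResult:
    term: str
    a: int  # subset genes with the term
    b: int  # subset genes without
    c: int  # non-subset universe genes with the term
    d: int  # non-subset universe genes without
    odds_ratio: float
    p_value: float
    p_bonferroni: float
    direction: str
    significant: bool


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sum of hypergeometric probabilities, over tables with the observed
    margins, that do not exceed the observed table's probability.
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def enrich_terms(
    subset: Iterable[str],
    annotations: Dict[str, Set[str]],
    universe: Optional[Iterable[str]] = None,
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Test every universe term for enrichment/depletion in ``subset``.

    ``universe`` defaults to all annotated genes.  Results are sorted by
    raw p-value; ``significant`` means Bonferroni-corrected p < ``alpha``.
    """
    uni: Set[str] = set(universe) if universe is not None else set(annotations)
    sub = set(subset)
    missing = sub - uni
    if missing:
        raise ValueError(f"subset genes absent from the universe: {sorted(missing)[:5]}")
    term_genes: Dict[str, Set[str]] = {}
    for gene in uni:
        for term in annotations.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    m = len(term_genes)
    n_sub = len(sub)
    n_uni = len(uni)
    results: List[EnrichmentResult] = []
    for term, genes in term_genes.items():
        a = len(genes & sub)
        b = n_sub - a
        c = len(genes) - a
        d = n_uni - n_sub - c
        p = fisher_exact_2x2(a, b, c, d)
        p_bonf = min(1.0, m * p)
        oddsr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        results.append(
            EnrichmentResult(
                term=term,
                a=a,
                b=b,
                c=c,
                d=d,
                odds_ratio=oddsr,
                p_value=p,
                p_bonferroni=p_bonf,
                direction="over" if oddsr > 1.0 else "under",
                significant=p_bonf < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
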
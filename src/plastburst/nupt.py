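"""Quantification of plastid-DNA insertions (NUPTs) in a nuclear assembly.

Works from a BLAST tabular hit set of the plastid genome scanned against
the nuclear assembly.  By default each hit counts as one insertion and the
total inserted length is the plain sum of hit alignment lengths (so
mean = total / n_hits); an optional merge mode unions overlapping subject
intervals per scaffold before totalling, which bounds the genome fraction
by one.  Also provides the Circos link table with min–max identity-ratio
colour bins and a scaffold-selection rule for circular plots, plus a toy
ungapped seed-and-extend aligner so synthetic fixtures need no external
aligner.

The recommended external scan is BLASTN with
``-max_target_seqs 1000 -dust no -evalue 1e-5 -penalty -2 -word_size 9``
(see :func:`blastn_command`); the package itself never requires BLAST.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core_io import AlignmentHit

__all__ = [
    "NuptSummary",
    "LinkRecord",
    "summarize_nupt",
    "select_plot_scaffolds",
    "color_links",
    "write_circos_links",
    "toy_local_align",
    "blastn_command",
    "revcomp",
]

BLASTN_PARAMS = "-max_target_seqs 1000 -dust no -evalue 1e-5 -penalty -2 -word_size 9"


@dataclass
class NuptSummary:
    n_hits: int
    n_scaffolds_hit: int
    total_aligned_bp: int
    genome_bp: int
    fraction: float
    min_len: int
    max_len: int
    mean_len: float
    median_len: float
    per_scaffold: Dict[str, int]
    n_scaffolds_over_2kb: int
    merged: bool


@dataclass
class LinkRecord:
    query_id: str
    qstart: int
    qend: int
    subject_id: str
    sstart: int
    send: int
    pct_identity: float
    ratio: float
    color: str


def _merged_lengths(hits: Sequence[AlignmentHit]) -> Dict[str, int]:
    """Union of subject intervals per scaffold, in bp (0-based half-open)."""
    by_scaf: Dict[str, List[Tuple[int, int]]] = {}
    for h in hits:
        by_scaf.setdefault(h.subject_id, []).append(h.subject_interval)
    out: Dict[str, int] = {}
    for scaf, ivals in by_scaf.items():
        ivals.sort()
        total = 0
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
        out[scaf] = total
    return out


def summarize_nupt(
    hits: Sequence[AlignmentHit],
    genome_bp: int,
    merge: bool = False,
    scaffold_lengths: Optional[Dict[str, int]] = None,
) -> NuptSummary:
    """Genome fraction and size-distribution statistics of a hit set."""
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    if scaffold_lengths is not None:
        unknown = {h.subject_id for h in hits} - set(scaffold_lengths)
        if unknown:
            raise ValueError(f"hits on unknown scaffolds: {sorted(unknown)}")
    if not hits:
        return NuptSummary(0, 0, 0, genome_bp, 0.0, 0, 0, 0.0, 0.0, {}, 0, merge)
    lengths = [h.aln_length for h in hits]
    if merge:
        per_scaffold = _merged_lengths(hits)
    else:
        per_scaffold = {}
        for h in hits:
            per_scaffold[h.subject_id] = per_scaffold.get(h.subject_id, 0) + h.aln_length
    total = sum(per_scaffold.values())
    return NuptSummary(
        n_hits=len(hits),
        n_scaffolds_hit=len(per_scaffold),
        total_aligned_bp=total,
        genome_bp=genome_bp,
        fraction=total / genome_bp,
        min_len=min(lengths),
        max_len=max(lengths),
        mean_len=sum(lengths) / len(lengths),
        median_len=float(statistics.median(lengths)),
        per_scaffold=per_scaffold,
        n_scaffolds_over_2kb=sum(1 for v in per_scaffold.values() if v > 2000),
        merged=merge,
    )


def select_plot_scaffolds(
    hits: Sequence[AlignmentHit],
    scaffold_lengths: Dict[str, int],
    plastid_bp: int,
    min_identity: float = 90.0,
    min_span: int = 2000,
) -> List[str]:
    """Scaffolds worth drawing on a circular plot.

    Selected iff the scaffold is at least as long as the plastid genome
    and carries at least one hit with identity >= ``min_identity`` over
    >= ``min_span`` bp; ordered by total aligned bp, descending (ties by
    name for determinism).
    """
    unknown = {h.subject_id for h in hits} - set(scaffold_lengths)
    if unknown:
        raise ValueError(f"missing lengths for scaffolds: {sorted(unknown)}")
    qualifying = {
        h.subject_id
        for h in hits
        if scaffold_lengths[h.subject_id] >= plastid_bp
        and h.pct_identity >= min_identity
        and h.aln_length >= min_span
    }
    totals: Dict[str, int] = {}
    for h in hits:
        if h.subject_id in qualifying:
            totals[h.subject_id] = totals.get(h.subject_id, 0) + h.aln_length
    return sorted(qualifying, key=lambda s: (-totals[s], s))


def color_links(hits: Sequence[AlignmentHit]) -> List[LinkRecord]:
    """Circoletto-style colour bins on the min–max identity ratio.

    ratio = (identity - min) / (max - min) over the hit set; bins:
    blue <= 0.25 < green <= 0.50 < orange <= 0.75 < red.  When all
    identities are equal the ratio is defined as 1 (red).
    """
    if not hits:
        raise ValueError("no hits to colour")
    ids = [h.pct_identity for h in hits]
    lo, hi = min(ids), max(ids)
    out = []
    for h in hits:
        ratio = 1.0 if hi == lo else (h.pct_identity - lo) / (hi - lo)
        if ratio <= 0.25:
            color = "blue"
        elif ratio <= 0.50:
            color = "green"
        elif ratio <= 0.75:
            color = "orange"
        else:
            color = "red"
        out.append(
            LinkRecord(
                query_id=h.query_id,
                qstart=h.qstart,
                qend=h.qend,
                subject_id=h.subject_id,
                sstart=h.sstart,
                send=h.send,
                pct_identity=h.pct_identity,
                ratio=ratio,
                color=color,
            )
        )
    return out


def write_circos_links(records: Sequence[LinkRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.qstart}\t{r.qend}\t"
                f"{r.subject_id}\t{r.sstart}\t{r.send}\tcolor={r.color}\n"
            )


def blastn_command(query_fasta: str, db: str, out_path: str) -> List[str]:
    """The documented external BLASTN invocation (outfmt 6)."""
    return (
        ["blastn", "-query", query_fasta, "-db", db, "-outfmt", "6", "-out", out_path]
        + BLASTN_PARAMS.split()
    )


# ---------------------------------------------------------------------------
# toy seed-and-extend aligner (fixtures only; not a BLASTN replacement)
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def toy_local_align(
    query: str,
    subject: str,
    word: int = 9,
    match: int = 1,
    mismatch: int = -2,
    xdrop: int = 20,
    min_score: int = 30,
    query_id: str = "query",
    subject_id: str = "subject",
) -> List[AlignmentHit]:
    """Exact-word seeding with ungapped two-sided x-drop extension.

    Both strands of the subject are scanned; seeds falling inside a region
    already extended on the same diagonal are skipped, and overlapping
    hits on one diagonal are merged.  Substitution-only: no gaps.
    """
    query = query.upper()
    subject = subject.upper()
    index: Dict[str, List[int]] = {}
    for qpos in range(len(query) - word + 1):
        index.setdefault(query[qpos : qpos + word], []).append(qpos)

    hits: List[AlignmentHit] = []
    for strand in "+-":
        subj = subject if strand == "+" else revcomp(subject)
        covered: Dict[int, int] = {}  # diagonal -> rightmost subj end extended
        raw: Dict[int, List[Tuple[int, int, int, int]]] = {}  # diag -> (s0, s1, q0, score)
        for spos in range(len(subj) - word + 1):
            qlist = index.get(subj[spos : spos + word])
            if not qlist:
                continue
            for qpos in qlist:
                diag = spos - qpos
                if covered.get(diag, -1) >= spos + word - 1:
                    continue
                s0, s1, q0, score, ident = _extend(
                    query, subj, qpos, spos, word, match, mismatch, xdrop
                )
                covered[diag] = max(covered.get(diag, -1), s1 - 1)
                if score >= min_score:
                    raw.setdefault(diag, []).append((s0, s1, q0, score))
        for diag, segs in raw.items():
            segs.sort()
            merged: List[List[int]] = []
            for s0, s1, q0, score in segs:
                if merged and s0 <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], s1)
                else:
                    merged.append([s0, s1, s0 - diag])
            for s0, s1, q0 in merged:
                length = s1 - s0
                n_match = sum(
                    1 for k in range(length) if query[q0 + k] == subj[s0 + k]
                )
                pct = 100.0 * n_match / length
                if strand == "+":
                    sstart, send = s0 + 1, s1
                else:
                    # map back to forward coordinates of the subject
                    sstart, send = len(subject) - s1 + 1, len(subject) - s0
                hits.append(
                    AlignmentHit(
                        query_id=query_id,
                        subject_id=subject_id,
                        pct_identity=pct,
                        aln_length=length,
                        mismatches=length - n_match,
                        gap_opens=0,
                        qstart=q0 + 1,
                        qend=q0 + length,
                        sstart=send if strand == "-" else sstart,
                        send=sstart if strand == "-" else send,
                        evalue=0.0,
                        bitscore=float(
                            n_match * match + (length - n_match) * mismatch
                        ),
                    )
                )
    return hits


def _extend(query, subj, qpos, spos, word, match, mismatch, xdrop):
    """Two-sided ungapped x-drop extension around an exact seed.

    Returns (s0, s1, q0, best_score, identity_fraction) with the segment
    trimmed back to the score maximum on each side.
    """
    # right extension (seed included at score word*match)
    score = best = word * match
    qi, si = qpos + word, spos + word
    best_r = (qi, si)
    while qi < len(query) and si < len(subj):
        score += match if query[qi] == subj[si] else mismatch
        qi += 1
        si += 1
        if score > best:
            best = score
            best_r = (qi, si)
        elif best - score > xdrop:
            break
    # left extension from the seed start
    score = best
    qi, si = qpos, spos
    best_l = (qi, si)
    while qi > 0 and si > 0:
        qi -= 1
        si -= 1
        score += match if query[qi] == subj[si] else mismatch
        if score > best:
            best = score
            best_l = (qi, si)
        elif best - score > xdrop:
            break
    q0, s0 = best_l
    q1, s1 = best_r
    length = s1 - s0
    n_match = sum(1 for k in range(length) if query[q0 + k] == subj[s0 + k])
    return s0, s1, q0, best, n_match / max(length, 1)
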
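"""Parsers, writers and tree utilities shared by the pipeline stages.

Trees are held in a small node/tree structure of our own so the likelihood
and weighting code can walk them cheaply; newick parsing, writing and
midpoint rooting are delegated to dendropy underneath.

Coordinate convention: BLAST tabular records are stored 1-based inclusive,
exactly as read; interval arithmetic (overlap merging) converts to 0-based
half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

import dendropy
from Bio import SeqIO

__all__ = [
    "TreeNode",
    "Tree",
    "SpeciesTree",
    "FamilyCounts",
    "AlignmentHit",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "midpoint_root",
    "resolve_polytomies",
    "read_blast_tab",
    "write_blast_tab",
    "read_counts_table",
    "read_annotations",
    "read_codon_fasta",
    "read_syntenic_pairs",
]


class NewickParseError(ValueError):
    """Raised for malformed newick input; message carries the position."""


class TreeNode:
    __slots__ = ("name", "length", "children", "parent", "branch_class")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None):
        self.name = name
        self.length = length
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None
        # branch class of the edge above this node; None on the root
        self.branch_class: Optional[str] = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, {self.length!r}, {len(self.children)} ch)"


class Tree:
    """Rooted tree with branch lengths; used for species and gene trees."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversals ----------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- metrics -------------------------------------------------------
    def depths(self) -> Dict[TreeNode, float]:
        """Root-to-node path lengths (root depth 0)."""
        d: Dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            d[node] = d[node.parent] + (node.length or 0.0)
        return d

    def leaf_distances(self) -> Dict[Tuple[str, str], float]:
        """All pairwise leaf-to-leaf path lengths, keyed by sorted name pair."""
        out: Dict[Tuple[str, str], float] = {}
        # at each internal node, combine leaf depth lists of child subtrees
        below: Dict[TreeNode, List[Tuple[str, float]]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = [(node.name, 0.0)]
            else:
                lists = [
                    [(n, d + (c.length or 0.0)) for n, d in below[c]]
                    for c in node.children
                ]
                for i in range(len(lists)):
                    for j in range(i + 1, len(lists)):
                        for a, da in lists[i]:
                            for b, db in lists[j]:
                                key = (a, b) if a <= b else (b, a)
                                out[key] = da + db
                below[node] = [x for lst in lists for x in lst]
        return out

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = self.depths()
        leaf_d = [d[n] for n in self.leaves()]
        top = max(leaf_d)
        if top == 0:
            return True
        return (top - min(leaf_d)) / top <= rel_tol

    def copy(self) -> "Tree":
        return parse_newick(write_newick(self))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.n_leaves()} leaves)"


class SpeciesTree(Tree):
    """Ultrametric species tree (branch lengths in Myr) with branch classes.

    Every non-root branch carries a class label, ``background`` by default;
    :meth:`set_foreground` marks the terminal branch of one species as
    ``foreground`` for branch-specific turnover models.
    """

    def __init__(self, root: TreeNode, ultrametric: bool = True):
        super().__init__(root)
        for node in self.postorder():
            if node is not self.root:
                node.branch_class = node.branch_class or "background"
        if ultrametric and not self.is_ultrametric():
            raise ValueError("tree flagged ultrametric but leaf depths differ")

    def set_foreground(self, species: str) -> None:
        for node in self.postorder():
            if node is not self.root:
                node.branch_class = "background"
        for leaf in self.leaves():
            if leaf.name == species:
                leaf.branch_class = "foreground"
                return
        raise KeyError(f"species {species!r} not a leaf of the tree")


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def _from_dendropy(dnode) -> TreeNode:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = TreeNode(name=label, length=dnode.edge.length)
    for ch in dnode.child_nodes():
        node.add(_from_dendropy(ch))
    return node


def parse_newick(text: str, species_tree: bool = False) -> Tree:
    """Parse one newick string into a :class:`Tree` (or :class:`SpeciesTree`).

    Polytomies are kept as read. Duplicate leaf names and syntax errors
    raise :class:`NewickParseError` with the offending position or name.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError flavours
        raise NewickParseError(f"newick parse error: {exc}") from None
    root = _from_dendropy(dtree.seed_node)
    tree = Tree(root)
    names = tree.leaf_names()
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise NewickParseError(f"duplicate leaf names: {', '.join(dup)}")
    if any(n is None for n in names):
        raise NewickParseError("unnamed leaf in newick input")
    if species_tree:
        return SpeciesTree(root)
    return tree


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        body = node.name or ""
    else:
        body = "(" + ",".join(_newick_node(c) for c in node.children) + ")"
        if node.name:
            body += node.name
    if node.length is not None:
        body += f":{node.length:.17g}"
    return body


def write_newick(tree: Tree) -> str:
    return _newick_node(tree.root) + ";"


def midpoint_root(tree: Tree) -> Tree:
    """Re-root at the midpoint of the longest leaf-to-leaf path.

    The input is treated as unrooted (a degree-2 root is suppressed);
    branch lengths are required on every edge and all path lengths are
    preserved.  When the midpoint falls exactly on an existing node that
    node becomes the root; otherwise a new root splits the edge.
    Returns a new tree.
    """
    if tree.n_leaves() < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    for node in tree.postorder():
        if node is not tree.root and node.length is None:
            raise ValueError("midpoint rooting requires branch lengths on all edges")

    # undirected adjacency over the original nodes
    adj: Dict[int, List[Tuple[TreeNode, float]]] = {}
    objs: Dict[int, TreeNode] = {}
    for n in tree.postorder():
        objs[id(n)] = n
        adj.setdefault(id(n), [])
        if n.parent is not None:
            adj[id(n)].append((n.parent, n.length))
            adj.setdefault(id(n.parent), []).append((n, n.length))
    old_root = tree.root
    if len(old_root.children) == 2:
        a, b = old_root.children
        through = a.length + b.length
        adj[id(a)] = [(x, l) for x, l in adj[id(a)] if x is not old_root] + [(b, through)]
        adj[id(b)] = [(x, l) for x, l in adj[id(b)] if x is not old_root] + [(a, through)]
        del adj[id(old_root)]

    def distances_from(start: TreeNode):
        dist = {id(start): 0.0}
        pred: Dict[int, TreeNode] = {}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, l in adj[id(u)]:
                if id(v) not in dist:
                    dist[id(v)] = dist[id(u)] + l
                    pred[id(v)] = u
                    stack.append(v)
        return dist, pred

    leaves = [n for n in objs.values() if id(n) in adj and len(adj[id(n)]) == 1]
    best = None
    for a in sorted(leaves, key=lambda n: n.name or ""):
        dist, pred = distances_from(a)
        for b in sorted(leaves, key=lambda n: n.name or ""):
            if a is b:
                continue
            d = dist[id(b)]
            if best is None or d > best[0] + 1e-15:
                best = (d, a, b, pred)
    diameter, a, b, pred = best

    # walk the a..b path from b back to a, then forward from a
    path = [b]
    while path[-1] is not a:
        path.append(pred[id(path[-1])])
    path.reverse()
    half = diameter / 2.0
    cum = 0.0
    for k in range(len(path) - 1):
        u, v = path[k], path[k + 1]
        elen = next(l for x, l in adj[id(u)] if x is v)
        if cum + elen >= half - 1e-12:
            break
        cum += elen

    def build(node: TreeNode, banned: List[TreeNode], length: Optional[float]) -> TreeNode:
        fresh = TreeNode(name=node.name, length=length)
        for nb, l in adj[id(node)]:
            if any(nb is bn for bn in banned):
                continue
            fresh.add(build(nb, [node], l))
        return fresh

    offset = half - cum  # distance from u toward v
    if offset <= 1e-12:  # midpoint sits on node u
        root = build(u, [], None)
    else:
        root = TreeNode(length=None)
        root.add(build(u, [v], offset))
        root.add(build(v, [u], elen - offset))
    return Tree(root)


def resolve_polytomies(tree: Tree) -> Tree:
    """Binarize in place: each polytomy becomes a left-leaning ladder of
    zero-length branches, children kept in their original left-to-right
    order (deterministic)."""
    for node in list(tree.postorder()):
        while len(node.children) > 2:
            a = node.children.pop(0)
            b = node.children.pop(0)
            merged = TreeNode(length=0.0)
            merged.add(a)
            merged.add(b)
            merged.parent = node
            node.children.insert(0, merged)
    return tree


# ---------------------------------------------------------------------------
# family counts
# ---------------------------------------------------------------------------

@dataclass
class FamilyCounts:
    """Gene counts per family (rows) and species (columns)."""

    family_ids: List[str]
    species: List[str]
    counts: "np.ndarray"  # (n_families, n_species) non-negative ints

    def __post_init__(self):
        import numpy as np

        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.family_ids), len(self.species)):
            raise ValueError("counts shape does not match family/species lists")
        if (self.counts < 0).any():
            raise ValueError("negative gene count")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not (self.counts == self.counts.astype(int)).all():
                raise ValueError("non-integer gene count")
            self.counts = self.counts.astype(int)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.counts.shape

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.family_ids, columns=self.species)

    def check_against_tree(self, tree: Tree) -> None:
        if set(self.species) != set(tree.leaf_names()):
            raise ValueError(
                "species in count table do not match tree leaves "
                f"(table only: {sorted(set(self.species) - set(tree.leaf_names()))}, "
                f"tree only: {sorted(set(tree.leaf_names()) - set(self.species))})"
            )


def read_counts_table(path) -> FamilyCounts:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        counts = df.to_numpy()
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"count table not numeric: {exc}") from None
    return FamilyCounts(list(df.index.astype(str)), list(df.columns.astype(str)), counts)


def write_counts_table(fc: FamilyCounts, path) -> None:
    fc.to_frame().to_csv(path, sep="\t", index_label="family_id")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

@dataclass
class AlignmentHit:
    """One local-alignment record (BLAST tabular outfmt-6 dialect).

    Subject coordinates are normalised so sstart <= send; a hit that was
    reported on the reverse strand keeps strand == "-".
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"

    def __post_init__(self):
        if not (1 <= self.qstart <= self.qend):
            raise ValueError(f"bad query interval {self.qstart}..{self.qend}")
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0,100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if self.sstart > self.send:
            self.sstart, self.send = self.send, self.sstart
            self.strand = "-"

    @property
    def subject_interval(self) -> Tuple[int, int]:
        """0-based half-open subject interval, for interval arithmetic."""
        return self.sstart - 1, self.send


def read_blast_tab(path) -> List[AlignmentHit]:
    hits: List[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(cols)}"
                )
            try:
                hit = AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            hits.append(hit)
    return hits


def write_blast_tab(hits: Sequence[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = h.sstart, h.send
            if h.strand == "-":
                sstart, send = send, sstart
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_length}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.qstart}\t{h.qend}\t"
                f"{sstart}\t{send}\t{h.evalue:.2g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# annotations, codon FASTA, syntenic pairs
# ---------------------------------------------------------------------------

def read_annotations(path) -> Dict[str, Set[str]]:
    """Two-column gene<TAB>GO-term table -> gene -> set of term ids."""
    ann: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
            gene, term = cols
            if not term:
                raise ValueError(f"{path}:{lineno}: empty term id")
            ann.setdefault(gene, set()).add(term)
    return ann


def read_codon_fasta(path) -> Dict[str, str]:
    """In-frame aligned codon FASTA -> {id: sequence}.

    All sequences must have equal length divisible by 3.
    """
    seqs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    (length,) = lengths
    if length % 3 != 0:
        raise ValueError(f"alignment length {length} not divisible by 3")
    return seqs


def read_syntenic_pairs(path) -> List[Tuple[str, str]]:
    pairs: List[Tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            pairs.append((cols[0], cols[1]))
    return pairs
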
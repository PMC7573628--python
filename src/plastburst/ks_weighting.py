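"""Redundancy correction of within-family Ks estimates by node weighting.

A family of n genes yields n(n-1)/2 pairwise Ks values for only n-1
duplication events, so raw pairwise distributions over-weight large
families.  Following the node-weighting idea of Vanneste-style corrections:
each midpoint-rooted family tree is first split recursively from the root
into child clades until no intra-clade pairwise Ks exceeds the saturation
threshold (default 5); then, for every duplication node of a retained
subclade with child-leaf sets of sizes a and b, each of the m = a*b
cross-pair Ks values enters the distribution with weight 1/m, so each
duplication event contributes total weight one.

Missing or saturation-flagged Ks values count as "> threshold" during
splitting and are skipped during weighting, with the node's weights
renormalised over its remaining cross pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core_io import Tree, TreeNode, resolve_polytomies

__all__ = [
    "WeightedKsSample",
    "KsMatrix",
    "split_by_ks",
    "node_weighted_ks",
    "build_weighted_distribution",
]


@dataclass
class WeightedKsSample:
    ks: float
    weight: float
    node_id: str
    family_id: str

    def __post_init__(self):
        if self.ks < 0:
            raise ValueError("negative Ks")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError("weight must be in (0, 1]")


class KsMatrix:
    """Symmetric pairwise Ks lookup; missing pairs return None."""

    def __init__(self, values: Dict[Tuple[str, str], Optional[float]]):
        self._d: Dict[Tuple[str, str], Optional[float]] = {}
        for (a, b), v in values.items():
            self._d[self._key(a, b)] = v

    @staticmethod
    def _key(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def get(self, a: str, b: str) -> Optional[float]:
        return self._d.get(self._key(a, b))

    @classmethod
    def from_frame(cls, df) -> "KsMatrix":
        vals: Dict[Tuple[str, str], Optional[float]] = {}
        for a in df.index:
            for b in df.columns:
                if a == b:
                    continue
                v = df.loc[a, b]
                vals[(str(a), str(b))] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
        return cls(vals)


def _as_matrix(ks) -> KsMatrix:
    if isinstance(ks, KsMatrix):
        return ks
    if isinstance(ks, dict):
        return KsMatrix(ks)
    return KsMatrix.from_frame(ks)


def _leaves_under(node: TreeNode) -> List[TreeNode]:
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(reversed(n.children))
    return out


def _clade_ok(node: TreeNode, ks: KsMatrix, threshold: float) -> bool:
    names = [l.name for l in _leaves_under(node)]
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            v = ks.get(names[i], names[j])
            if v is None or v > threshold:
                return False
    return True


def split_by_ks(tree: Tree, ks, threshold: float = 5.0) -> List[TreeNode]:
    """Partition the leaves into maximal subclades with all internal
    pairwise Ks <= threshold, splitting from the root downwards.

    Returns the subtree roots of the retained subclades (singletons
    included; they carry no duplication node and contribute no samples).
    """
    ksm = _as_matrix(ks)
    resolve_polytomies(tree)
    out: List[TreeNode] = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        if node.is_leaf or _clade_ok(node, ksm, threshold):
            out.append(node)
        else:
            stack.extend(reversed(node.children))
    return out


def node_weighted_ks(
    subclade: TreeNode, ks, family_id: str = "", node_prefix: str = "n"
) -> List[WeightedKsSample]:
    """Weighted samples from every duplication node of one subclade.

    Each internal node with a and b leaves in its two child subtrees
    yields its a*b cross-pair Ks values at weight 1/(a*b); pairs with
    missing Ks are dropped and the node's weights renormalised so the
    node still sums to one when any pair remains.
    """
    ksm = _as_matrix(ks)
    samples: List[WeightedKsSample] = []
    counter = 0
    stack = [subclade]
    internal: List[TreeNode] = []
    while stack:
        n = stack.pop()
        if not n.is_leaf:
            internal.append(n)
            stack.extend(n.children)
    for node in reversed(internal):
        if len(node.children) != 2:
            raise ValueError("duplication-node weighting requires a binary subclade")
        left = [l.name for l in _leaves_under(node.children[0])]
        right = [l.name for l in _leaves_under(node.children[1])]
        vals = [
            ksm.get(a, b)
            for a in left
            for b in right
        ]
        defined = [v for v in vals if v is not None]
        counter += 1
        if not defined:
            continue
        w = 1.0 / len(defined)
        nid = f"{node_prefix}{counter}"
        for v in defined:
            samples.append(WeightedKsSample(ks=max(v, 0.0), weight=w, node_id=nid, family_id=family_id))
    return samples


def build_weighted_distribution(
    families: Sequence[Tuple[str, Tree, object]], threshold: float = 5.0
) -> List[WeightedKsSample]:
    """Concatenate node-weighted samples over (family_id, tree, ks) triples.

    Trees must be rooted (midpoint-root unrooted input first); families
    with fewer than two leaves are skipped.
    """
    out: List[WeightedKsSample] = []
    for fam_id, tree, ks in families:
        if tree.n_leaves() < 2:
            continue
        for ci, clade in enumerate(split_by_ks(tree, ks, threshold)):
            out.extend(
                node_weighted_ks(clade, ks, family_id=fam_id, node_prefix=f"{fam_id}.c{ci}.n")
            )
    return out
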
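"""Variable-group agglomerative hierarchical clustering (multidendrograms).

Classical pair-group agglomeration breaks ties arbitrarily, so the output
tree can depend on input order.  The variable-group method instead merges
*all* clusters tied at the minimal distance simultaneously, producing nodes
with two or more children and an agglomeration band ``[band_low, band_high]``
— the interval of pairwise distances fused in that merge.  The result is
invariant under permutation of the input.

Five linkage methods are provided: single, complete, unweighted and weighted
average (UPGMA / WPGMA generalized to multi-way merges), and Joint
Between-Within, which scores a candidate fusion by the root-mean-square
leaf-to-leaf dissimilarity over every pair drawn from the union of the two
clusters — between-cluster and within-cluster pairs alike.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import UsageError
from .metrics import DissimilarityMatrix

LINKAGE_METHODS = (
    "single", "complete", "average_unweighted", "average_weighted",
    "joint_between_within",
)


@dataclass(frozen=True)
class LinkageSpec:
    """Linkage method plus the tie tolerance of the variable-group merge.

    ``tie_epsilon`` is a relative tolerance: distances within
    ``tie_epsilon * max(|d*|, 1)`` of the round minimum ``d*`` count as tied.
    Exact ties in rational inputs are always caught; the default absorbs only
    floating-point summation noise.
    """

    method: str = "average_unweighted"
    tie_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.method not in LINKAGE_METHODS:
            raise UsageError(
                f"unknown linkage method {self.method!r}; choose from {LINKAGE_METHODS}"
            )
        if self.tie_epsilon < 0:
            raise UsageError("tie_epsilon must be non-negative")


@dataclass
class TreeNode:
    """A node of a multidendrogram.

    Leaves carry ``name`` and height 0.  Internal nodes carry >= 2 children
    and the agglomeration band; ``band_low`` is the threshold at which the
    merge happened and serves as the node's ultrametric height.
    """

    name: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)
    band_low: float = 0.0
    band_high: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def height(self) -> float:
        return 0.0 if self.is_leaf else self.band_low

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name or ""]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaf_names())
        return out

    def sort_key(self) -> str:
        return self.name if self.is_leaf else min(c.sort_key() for c in self.children)


@dataclass
class Multidendrogram:
    """A rooted context tree over named leaves."""

    root: TreeNode
    linkage: LinkageSpec

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def __len__(self) -> int:
        return len(self.leaf_names())


def linkage_update(
    method: str,
    member_distances: Sequence[float],
    member_sizes: Sequence[int],
) -> float:
    """Distance from a freshly merged cluster to another cluster K.

    ``member_distances[i]`` is the distance from the i-th member of the
    merged set to K; ``member_sizes[i]`` is that member's leaf count.
    Not applicable to joint_between_within, which is computed from the
    original leaf-to-leaf matrix rather than from member distances.
    """
    if not member_distances or len(member_distances) != len(member_sizes):
        raise UsageError("member distance and size lists must be non-empty and equal length")
    d = np.asarray(member_distances, dtype=float)
    s = np.asarray(member_sizes, dtype=float)
    if method == "single":
        return float(d.min())
    if method == "complete":
        return float(d.max())
    if method == "average_unweighted":
        return float((d * s).sum() / s.sum())
    if method == "average_weighted":
        return float(d.mean())
    if method == "joint_between_within":
        raise UsageError(
            "joint_between_within is computed from the leaf-level matrix, "
            "not via member-distance updates"
        )
    raise UsageError(f"unknown linkage method {method!r}")


class _Cluster:
    __slots__ = ("node", "leaves", "size")

    def __init__(self, node: TreeNode, leaves: frozenset[int]):
        self.node = node
        self.leaves = leaves
        self.size = len(leaves)


def _jbw_distance(base_sq: np.ndarray, leaves_a: frozenset[int], leaves_b: frozenset[int]) -> float:
    """Root-mean-square leaf dissimilarity over all pairs within the union."""
    idx = sorted(leaves_a | leaves_b)
    sub = base_sq[np.ix_(idx, idx)]
    n = len(idx)
    if n < 2:
        return 0.0
    total = sub.sum() / 2.0  # upper triangle sum of squared dissimilarities
    return math.sqrt(total / (n * (n - 1) / 2.0))


def _components(n: int, edges: list[tuple[int, int]]) -> list[list[int]]:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return [comps[r] for r in sorted(comps)]


def cluster(M: DissimilarityMatrix, link: LinkageSpec = LinkageSpec()) -> Multidendrogram:
    """Agglomerate a dissimilarity matrix into a multidendrogram.

    Each round finds the global minimum inter-cluster distance ``d*``, joins
    every connected component of the graph of pairs tied with ``d*`` into one
    node (band ``[d*, max in-component distance]``), and updates distances
    under the linkage method.  Deterministic and invariant under leaf
    permutation.
    """
    n = len(M)
    if n < 2:
        raise UsageError("clustering requires at least 2 leaves")

    base = np.asarray(M.values, dtype=float)
    base_sq = base ** 2
    clusters = [
        _Cluster(TreeNode(name=nm), frozenset([i])) for i, nm in enumerate(M.leaves)
    ]
    dist = base.copy()

    while len(clusters) > 1:
        m = len(clusters)
        iu = np.triu_indices(m, k=1)
        d_star = float(dist[iu].min())
        tol = link.tie_epsilon * max(abs(d_star), 1.0)
        edges = [
            (int(i), int(j))
            for i, j in zip(*iu)
            if dist[i, j] <= d_star + tol
        ]
        comps = _components(m, edges)

        new_clusters: list[_Cluster] = []
        membership: list[list[int]] = []  # old indices per new cluster
        for comp in comps:
            if len(comp) == 1:
                new_clusters.append(clusters[comp[0]])
                membership.append(comp)
                continue
            internal = [dist[i, j] for k, i in enumerate(comp) for j in comp[k + 1:]]
            children = sorted(
                (clusters[i].node for i in comp), key=TreeNode.sort_key
            )
            node = TreeNode(
                children=children,
                band_low=d_star,
                band_high=float(max(internal)),
            )
            leaves = frozenset().union(*(clusters[i].leaves for i in comp))
            new_clusters.append(_Cluster(node, leaves))
            membership.append(comp)

        k = len(new_clusters)
        new_dist = np.zeros((k, k), dtype=float)
        for a in range(k):
            for b in range(a + 1, k):
                if link.method == "joint_between_within":
                    d = _jbw_distance(
                        base_sq, new_clusters[a].leaves, new_clusters[b].leaves
                    )
                else:
                    # fold member-to-member distances of the previous round:
                    # first each member of A against all of B, then across A
                    rows = []
                    for i in membership[a]:
                        ds = [dist[i, j] for j in membership[b]]
                        sizes = [clusters[j].size for j in membership[b]]
                        rows.append(linkage_update(link.method, ds, sizes))
                    d = linkage_update(
                        link.method, rows, [clusters[i].size for i in membership[a]]
                    )
                new_dist[a, b] = new_dist[b, a] = d
        clusters = new_clusters
        dist = new_dist

    root = clusters[0].node
    if root.is_leaf:  # cannot happen for n >= 2
        raise UsageError("degenerate clustering result")
    _sort_children(root)
    return Multidendrogram(root, link)


def _sort_children(node: TreeNode) -> None:
    if node.is_leaf:
        return
    node.children.sort(key=TreeNode.sort_key)
    for c in node.children:
        _sort_children(c)


_NEWICK_SAFE = frozenset(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-"
)


def _quote(name: str) -> str:
    if name and all(ch in _NEWICK_SAFE for ch in name):
        return name
    return "'" + name.replace("'", "''") + "'"


def to_newick(t: Multidendrogram, height_mode: str = "band_low") -> str:
    """Serialize to Newick with branch lengths from node heights.

    Leaves sit at height 0; an internal node's height is its ``band_low``
    (or the band midpoint with ``height_mode='band_mid'``); a branch length
    is the parent-child height difference.  Multifurcations are preserved.
    """
    if height_mode not in ("band_low", "band_mid"):
        raise UsageError(f"unknown height mode {height_mode!r}")

    def height(node: TreeNode) -> float:
        if node.is_leaf:
            return 0.0
        if height_mode == "band_mid":
            return (node.band_low + node.band_high) / 2.0
        return node.band_low

    def fmt(x: float) -> str:
        s = f"{x:.10g}"
        return s

    def render(node: TreeNode, parent_h: Optional[float]) -> str:
        if node.is_leaf:
            body = _quote(node.name or "")
        else:
            body = "(" + ",".join(render(c, height(node)) for c in node.children) + ")"
        if parent_h is None:
            return body
        return body + ":" + fmt(max(parent_h - height(node), 0.0))

    return render(t.root, None) + ";"


def select_leaves(t: Multidendrogram, name_filter: str = "") -> list[str]:
    """Leaf names matching a case-insensitive substring filter.

    An empty filter selects every leaf ("select all" semantics).
    """
    names = t.leaf_names()
    if not name_filter:
        return names
    needle = name_filter.lower()
    return [nm for nm in names if needle in nm.lower()]


def to_json(t: Multidendrogram) -> str:
    """JSON tree dump carrying the agglomeration band of every node."""

    def node_dict(node: TreeNode) -> dict:
        if node.is_leaf:
            return {"leaf": node.name}
        return {
            "band_low": node.band_low,
            "band_high": node.band_high,
            "children": [node_dict(c) for c in node.children],
        }

    return json.dumps(
        {"linkage": t.linkage.method, "tree": node_dict(t.root)}, indent=2
    )
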
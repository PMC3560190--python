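"""Independent reference implementations used to cross-check the package.

Everything here deliberately takes a different route from the library code:
scipy's pair-group agglomerative clustering, a sparse-graph minimum spanning
tree, and a brute-force gap comparison.
"""

import numpy as np
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform


def scipy_clades(matrix: np.ndarray, method: str):
    """Clades and merge heights from scipy's binary agglomerative clustering.

    Returns a set of (frozenset of leaf indices, height) for every internal
    node.
    """
    Z = scipy_linkage(squareform(matrix, checks=False), method=method)
    n = matrix.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    clades = []
    for row_idx, (a, b, h, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        clades.append((merged, float(h)))
    return clades


def tree_clades(tree, leaf_index: dict):
    """(frozenset of leaf indices, band_low) for every internal node."""
    out = []

    def walk(node):
        if node.is_leaf:
            return frozenset([leaf_index[node.name]])
        leaves = frozenset()
        for c in node.children:
            leaves |= walk(c)
        out.append((leaves, node.band_low))
        return leaves

    walk(tree.root)
    return out


def clades_equal(a, b, tol=1e-9):
    """Same clade families with matching heights."""
    da = {fs: h for fs, h in a}
    db = {fs: h for fs, h in b}
    if set(da) != set(db):
        return False
    return all(abs(da[fs] - db[fs]) <= tol for fs in da)


def mst_edge_weights(matrix: np.ndarray):
    """Sorted minimum-spanning-tree edge weights of a distance matrix."""
    mst = minimum_spanning_tree(matrix)
    return sorted(np.asarray(mst[mst.nonzero()]).ravel().tolist())


def brute_force_gap_distance(genes_a, genes_b):
    """Mean absolute difference of adjacent intergenic gaps, by direct loop.

    Assumes both gene lists have identical content and order (the regime the
    cross-check targets); gaps measured between consecutive gene boundaries.
    """
    assert len(genes_a) == len(genes_b) >= 2

    def gaps(genes):
        ordered = sorted(genes, key=lambda g: g.start)
        return [
            ordered[i + 1].start - ordered[i].end - 1
            for i in range(len(ordered) - 1)
        ]
    ga, gb = gaps(genes_a), gaps(genes_b)
    return sum(abs(x - y) for x, y in zip(ga, gb)) / len(ga)
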
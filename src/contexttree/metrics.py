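"""Context-to-context dissimilarity metrics and the pairwise matrix.

Four metrics are provided.  Dice and Jaccard treat a grouping as the set of
its genes' identity keys (homology cluster IDs, or normalized annotation
strings) and measure gene-content difference; they suit large groupings.
Moving Distances compares the order and intergenic spacing of the genes two
groupings share, for groupings with similar content but shifted spacing.
Total Length compares only the genomic extent of the groupings, useful for
one- or few-gene groupings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .errors import UsageError
from .model import ContextGrouping, GeneFeature

METRICS = ("dice", "jaccard", "moving_distances", "total_length")
COMPARISON_KEYS = ("homology_cluster", "annotation")

#: Sentinel dissimilarity when two groupings share fewer than two genes and
#: spacing comparison is therefore undefined.
DEFAULT_MOVING_CAP = 10_000.0


def normalize_annotation(text: str) -> str:
    """Canonical annotation key: lowercase, whitespace collapsed."""
    return re.sub(r"\s+", " ", text.strip().lower())


def identity_key(gene: GeneFeature, key: str) -> Hashable | None:
    """The cross-genome identity of one gene under a comparison key.

    Genes without a homology-cluster assignment have no identity under the
    ``homology_cluster`` key and are left out of set comparisons.
    """
    if key == "homology_cluster":
        return gene.homology_cluster
    if key == "annotation":
        return normalize_annotation(gene.annotation) or None
    raise UsageError(f"unknown comparison key {key!r}")


def gene_identity_set(grouping: ContextGrouping, key: str) -> frozenset:
    """Reduce a grouping to the set of its genes' identity keys."""
    return frozenset(
        k for g in grouping.genes if (k := identity_key(g, key)) is not None
    )


def dice(a: frozenset | set, b: frozenset | set) -> float:
    """Dice dissimilarity 1 - 2|a∩b|/(|a|+|b|); 0 when both sets are empty."""
    if not a and not b:
        return 0.0
    return 1.0 - 2.0 * len(a & b) / (len(a) + len(b))


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Jaccard dissimilarity 1 - |a∩b|/|a∪b|; 0 when both sets are empty."""
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def _oriented_genes(grouping: ContextGrouping, mirror_minus: bool) -> list[GeneFeature]:
    """Gene list in comparison orientation.

    With ``mirror_minus``, a grouping whose genes are mostly on the reverse
    strand is read right-to-left, so analogous contexts encoded on opposite
    strands compare in a common orientation (strand normalization).
    """
    genes = list(grouping.genes)
    if mirror_minus:
        minus = sum(1 for g in genes if g.strand == "-")
        if minus * 2 > len(genes):
            genes.reverse()
    return genes


def _facing_gap(left: GeneFeature, right: GeneFeature) -> int:
    """Nucleotides between the facing boundaries of two ordered genes."""
    lo = min((left.start, left.end), (right.start, right.end))
    hi = max((left.start, left.end), (right.start, right.end))
    return hi[0] - lo[1] - 1


def moving_distances(
    a: ContextGrouping,
    b: ContextGrouping,
    key: str = "homology_cluster",
    penalty_P: float = 0.0,
    default_cap: float = DEFAULT_MOVING_CAP,
    mirror_minus: bool = True,
) -> float:
    """Order-and-spacing dissimilarity between two groupings.

    Each grouping's ordered gene list is restricted to identity keys present
    in both, matching repeated keys in positional order.  For every adjacent
    pair of the shared subsequence the intergenic gap is measured within each
    grouping; the dissimilarity is the mean absolute gap difference, plus
    ``penalty_P`` per unshared gene.  Fewer than two shared genes leaves no
    spacing to compare, and the configured sentinel ``default_cap`` is
    returned.
    """
    if a.genes == b.genes:
        return 0.0
    genes_a = _oriented_genes(a, mirror_minus)
    genes_b = _oriented_genes(b, mirror_minus)
    keys_a = [identity_key(g, key) for g in genes_a]
    keys_b = [identity_key(g, key) for g in genes_b]

    # match repeated keys by occurrence index, in positional order
    from collections import Counter

    shared_count = Counter(k for k in keys_a if k is not None) & Counter(
        k for k in keys_b if k is not None
    )

    def shared_subsequence(genes: list[GeneFeature], keys: list) -> list[GeneFeature]:
        budget = dict(shared_count)
        out = []
        for g, k in zip(genes, keys):
            if budget.get(k, 0) > 0:
                out.append(g)
                budget[k] -= 1
        return out

    sub_a = shared_subsequence(genes_a, keys_a)
    sub_b = shared_subsequence(genes_b, keys_b)
    n_unshared = (len(genes_a) - len(sub_a)) + (len(genes_b) - len(sub_b))

    if len(sub_a) < 2:
        return float(default_cap)

    gaps_a = [_facing_gap(sub_a[i], sub_a[i + 1]) for i in range(len(sub_a) - 1)]
    gaps_b = [_facing_gap(sub_b[i], sub_b[i + 1]) for i in range(len(sub_b) - 1)]
    d = float(np.mean([abs(ga - gb) for ga, gb in zip(gaps_a, gaps_b)]))
    return d + penalty_P * n_unshared


def total_length(
    a: ContextGrouping, b: ContextGrouping, mode: str = "span"
) -> float:
    """Absolute difference of grouping lengths, in nucleotides.

    ``span`` measures the genomic envelope (default); ``gene_sum`` instead
    sums individual gene lengths, ignoring intergenic nucleotides.
    """
    if mode == "span":
        la, lb = a.span_length, b.span_length
    elif mode == "gene_sum":
        la = sum(g.length for g in a.genes)
        lb = sum(g.length for g in b.genes)
    else:
        raise UsageError(f"unknown total_length mode {mode!r}")
    return float(abs(la - lb))


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise dissimilarities over named context-tree leaves."""

    leaves: list[str]
    values: np.ndarray
    metric: str = "dice"
    comparison_key: str = "homology_cluster"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.leaves)
        if self.values.shape != (n, n):
            raise UsageError("matrix shape does not match leaf count")
        if not np.allclose(self.values, self.values.T, rtol=0, atol=1e-12):
            raise UsageError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise UsageError("dissimilarity matrix must have a zero diagonal")
        if (self.values < -1e-12).any():
            raise UsageError("dissimilarities must be non-negative")

    def __len__(self) -> int:
        return len(self.leaves)

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("leaf\t" + "\t".join(self.leaves) + "\n")
            for name, row in zip(self.leaves, self.values):
                fh.write(name + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    def to_phylip(self, path: str) -> None:
        """Square PHYLIP distance-matrix format (names truncated to 10 chars)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.leaves)}\n")
            for name, row in zip(self.leaves, self.values):
                fh.write(f"{name[:10]:<10} " + " ".join(f"{v:.6f}" for v in row) + "\n")


def build_matrix(
    leaves: Sequence[ContextGrouping],
    metric: str = "dice",
    key: str = "homology_cluster",
    penalty_P: float = 0.0,
    default_cap: float = DEFAULT_MOVING_CAP,
    mirror_minus: bool = True,
    length_mode: str = "span",
) -> DissimilarityMatrix:
    """Compute the full pairwise dissimilarity matrix for a list of leaves."""
    if metric not in METRICS:
        raise UsageError(f"unknown metric {metric!r}; choose from {METRICS}")
    if key not in COMPARISON_KEYS:
        raise UsageError(f"unknown comparison key {key!r}")
    if len(leaves) < 2:
        raise UsageError("a dissimilarity matrix needs at least 2 leaves")

    n = len(leaves)
    values = np.zeros((n, n), dtype=float)
    if metric in ("dice", "jaccard"):
        sets = [gene_identity_set(g, key) for g in leaves]
        fn = dice if metric == "dice" else jaccard
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = fn(sets[i], sets[j])
    elif metric == "moving_distances":
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = moving_distances(
                    leaves[i], leaves[j], key=key, penalty_P=penalty_P,
                    default_cap=default_cap, mirror_minus=mirror_minus,
                )
    else:
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = total_length(
                    leaves[i], leaves[j], mode=length_mode
                )
    names = [g.leaf_name or f"leaf{i+1}" for i, g in enumerate(leaves)]
    return DissimilarityMatrix(names, values, metric=metric, comparison_key=key)
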
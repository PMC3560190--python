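"""Core data model: genes, genomes, homology maps, context groupings and trees.

Coordinates follow the GFF convention throughout: 1-based, inclusive on both
ends.  A gene spanning positions 100..400 is 301 nt long, and the intergenic
gap between genes ending at 400 and starting at 416 is 15 nt (positions
401..415 lie strictly between them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .errors import UsageError

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on one contig.

    ``homology_cluster`` is the integer ID of the cross-species homologous
    gene cluster this gene belongs to (computed upstream, e.g. BLAST + MCL);
    ``None`` when no assignment is known.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    annotation: str = ""
    homology_cluster: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_cluster(self, cluster: Optional[int]) -> "GeneFeature":
        return GeneFeature(
            self.gene_id, self.contig, self.start, self.end,
            self.strand, self.annotation, cluster,
        )


def intergenic_gap(left: GeneFeature, right: GeneFeature) -> int:
    """Nucleotides strictly between two genes; negative when they overlap.

    ``gap == 0`` means the genes abut (right starts at left.end + 1).
    """
    return right.start - left.end - 1


@dataclass
class Genome:
    """One annotated genome: a species name and its position-sorted genes."""

    species_name: str
    features: list[GeneFeature] = field(default_factory=list)
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = sorted(
            self.features, key=lambda f: (f.contig, f.start, f.end, f.gene_id)
        )
        seen: set[str] = set()
        for f in self.features:
            if f.gene_id in seen:
                raise ValueError(
                    f"genome {self.species_name!r}: duplicate gene_id {f.gene_id!r}"
                )
            seen.add(f.gene_id)
        self._by_id = {f.gene_id: f for f in self.features}

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, gene_id: str) -> Optional[GeneFeature]:
        return self._by_id.get(gene_id)

    def contigs(self) -> list[str]:
        out: list[str] = []
        for f in self.features:
            if not out or out[-1] != f.contig:
                out.append(f.contig)
        return out

    def contig_features(self, contig: str) -> list[GeneFeature]:
        return [f for f in self.features if f.contig == contig]

    def with_homology(self, assignments: dict[str, int]) -> "Genome":
        """Return a copy whose genes carry cluster IDs from ``assignments``."""
        feats = [f.with_cluster(assignments.get(f.gene_id, f.homology_cluster))
                 for f in self.features]
        return Genome(self.species_name, feats, dict(self.contig_lengths))


@dataclass
class HomologyMap:
    """Cross-species homology clusters: (species, gene_id) -> cluster ID."""

    assignments: dict[tuple[str, str], int] = field(default_factory=dict)

    def cluster_of(self, species: str, gene_id: str) -> Optional[int]:
        return self.assignments.get((species, gene_id))

    def annotate(self, genomes: Iterable[Genome]) -> list[Genome]:
        """Stamp cluster IDs onto gene features of each genome."""
        out = []
        for g in genomes:
            per_gene = {
                gid: cl for (sp, gid), cl in self.assignments.items()
                if sp == g.species_name
            }
            out.append(g.with_homology(per_gene))
        return out


@dataclass
class ContextGrouping:
    """An ordered run of genes from one genome: one leaf of a context tree."""

    species_name: str
    contig: str
    genes: list[GeneFeature]
    leaf_name: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a context grouping must contain at least one gene")
        if any(g.contig != self.contig for g in self.genes):
            raise ValueError("all genes of a grouping must share one contig")
        self.genes = sorted(self.genes, key=lambda f: (f.start, f.end, f.gene_id))

    @property
    def span_start(self) -> int:
        return min(g.start for g in self.genes)

    @property
    def span_end(self) -> int:
        return max(g.end for g in self.genes)

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start + 1

    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)


# Grouping schemes a ContextSet may use.
SCHEMES = (
    "single_gene", "operon", "gene_window", "nt_window", "strand_distance", "custom",
)


@dataclass(frozen=True)
class ContextSet:
    """A named grouping scheme with its parameters.

    Parameters by scheme: ``operon`` — intergenic threshold ``threshold_nt``
    (default 20 nt); ``strand_distance`` — chaining distance ``distance_nt``
    (the "D75" set of the original study is this scheme at 75 nt);
    ``gene_window`` — ``k_genes`` neighbors each side; ``nt_window`` —
    ``window_nt`` each side of a match.
    """

    name: str
    scheme: str
    threshold_nt: int = 20
    distance_nt: int = 75
    k_genes: int = 0
    window_nt: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise UsageError(f"unknown context-set scheme {self.scheme!r}")
        for attr in ("threshold_nt", "distance_nt", "k_genes", "window_nt"):
            v = getattr(self, attr)
            if not isinstance(v, int) or v < 0:
                raise UsageError(f"context set {self.name!r}: {attr} must be a non-negative integer")


@dataclass(frozen=True)
class Query:
    """A search over loaded genomes.

    ``annotation_text`` mode does substring matching against gene annotations
    (case-insensitive unless ``case_sensitive``); ``homology_cluster_id`` mode
    matches genes by exact cluster ID.
    """

    mode: str
    value: str | int
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("annotation_text", "homology_cluster_id"):
            raise UsageError(f"unknown query mode {self.mode!r}")
        if self.mode == "homology_cluster_id":
            object.__setattr__(self, "value", int(self.value))
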
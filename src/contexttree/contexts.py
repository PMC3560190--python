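"""Build context groupings from genomes and retrieve those matching a query.

The central primitive is same-strand chaining: consecutive genes on one
contig and one strand whose intergenic gap does not exceed a threshold are
chained, transitively, into one grouping.  With a threshold of 20 nt this is
the classic intergenic-distance operon prediction; at 75 nt it is the "D75"
context set used in the ggt/hpxW case study.
"""

from __future__ import annotations

import re
from typing import Optional, Sequence

from .errors import NoMatchesError, UsageError
from .model import (
    ContextGrouping,
    ContextSet,
    GeneFeature,
    Genome,
    HomologyMap,
    Query,
    intergenic_gap,
)


def _chain_same_strand(genome: Genome, threshold: int) -> list[ContextGrouping]:
    """Partition a genome into same-strand runs with gaps <= threshold.

    Chains break at contig boundaries and strand switches; overlapping genes
    (negative gap) always chain.  Every gene lands in exactly one grouping.
    """
    if threshold < 0:
        raise UsageError("chaining threshold must be >= 0")
    groupings: list[ContextGrouping] = []
    run: list[GeneFeature] = []
    for feat in genome.features:
        if run and (
            feat.contig != run[-1].contig
            or feat.strand != run[-1].strand
            or intergenic_gap(run[-1], feat) > threshold
        ):
            groupings.append(ContextGrouping(genome.species_name, run[0].contig, run))
            run = []
        run.append(feat)
    if run:
        groupings.append(ContextGrouping(genome.species_name, run[0].contig, run))
    return groupings


def group_operons(genome: Genome, threshold_T: int = 20) -> list[ContextGrouping]:
    """Predict operons by intergenic distance (default threshold 20 nt)."""
    return _chain_same_strand(genome, threshold_T)


def group_strand_distance(genome: Genome, D: int = 75) -> list[ContextGrouping]:
    """Chain same-strand genes within D nt of each other (D75 at D=75).

    Identical rule to :func:`group_operons`; the two names reflect the two
    grouping schemes users select between.
    """
    return _chain_same_strand(genome, D)


def match_query(
    genomes: Sequence[Genome],
    homology: Optional[HomologyMap],
    q: Query,
) -> list[tuple[Genome, GeneFeature]]:
    """Find all genes matching a query, in (species order, contig, start) order."""
    if q.mode == "homology_cluster_id" and homology is None:
        # feature-embedded cluster IDs also count as homology information
        if not any(
            f.homology_cluster is not None for genome in genomes for f in genome
        ):
            raise UsageError("a homology-cluster query requires homology information")
    matches: list[tuple[Genome, GeneFeature]] = []
    for genome in genomes:
        for feat in genome.features:
            if q.mode == "annotation_text":
                needle, hay = str(q.value), feat.annotation
                if not q.case_sensitive:
                    needle, hay = needle.lower(), hay.lower()
                if needle in hay:
                    matches.append((genome, feat))
            else:
                cluster = feat.homology_cluster
                if cluster is None and homology is not None:
                    cluster = homology.cluster_of(genome.species_name, feat.gene_id)
                if cluster == q.value:
                    matches.append((genome, feat))
    return matches


def name_leaf(species_name: str, serial: int) -> str:
    """Leaf name: species name and per-species match serial, '-'-joined.

    Whitespace in species names is replaced by '_' so names survive Newick.
    """
    if serial < 1:
        raise UsageError("leaf serial numbers start at 1")
    return re.sub(r"\s+", "_", species_name.strip()) + f"-{serial}"


def build_context_leaves(
    genomes: Sequence[Genome],
    homology: Optional[HomologyMap],
    q: Query,
    cs: ContextSet,
    custom_groupings: Optional[Sequence[ContextGrouping]] = None,
) -> list[ContextGrouping]:
    """Resolve a query to named context-tree leaves under a grouping scheme.

    Every matched gene contributes the grouping that contains it.  A grouping
    hit by several matches appears once, with the serial of its first match.
    Serials count matches per species in (contig, start) order, starting at 1.
    Raises :class:`NoMatchesError` when the query matches nothing anywhere.
    """
    matches = match_query(genomes, homology, q)
    if not matches:
        raise NoMatchesError(f"query {q.mode}={q.value!r} matched no gene in any genome")

    # precompute the partition for partition-based schemes, per genome
    partitions: dict[str, dict[str, ContextGrouping]] = {}
    if cs.scheme in ("operon", "strand_distance"):
        threshold = cs.threshold_nt if cs.scheme == "operon" else cs.distance_nt
        for genome in genomes:
            lookup: dict[str, ContextGrouping] = {}
            for grp in _chain_same_strand(genome, threshold):
                for gene in grp.genes:
                    lookup[gene.gene_id] = grp
            partitions[genome.species_name] = lookup
    elif cs.scheme == "custom":
        if custom_groupings is None:
            raise UsageError("the custom scheme requires loaded custom groupings")
        for grp in custom_groupings:
            lookup = partitions.setdefault(grp.species_name, {})
            for gene in grp.genes:
                lookup[gene.gene_id] = grp

    serial_counter: dict[str, int] = {}
    leaves: list[ContextGrouping] = []
    seen_groupings: dict[tuple[str, tuple[str, ...]], bool] = {}
    for genome, feat in matches:
        sp = genome.species_name
        serial_counter[sp] = serial_counter.get(sp, 0) + 1
        serial = serial_counter[sp]

        if cs.scheme == "single_gene":
            grouping = ContextGrouping(sp, feat.contig, [feat])
        elif cs.scheme in ("operon", "strand_distance", "custom"):
            grouping = partitions.get(sp, {}).get(feat.gene_id)
            if grouping is None:
                if cs.scheme == "custom":
                    continue  # match outside any custom grouping: no context
                raise UsageError(f"gene {feat.gene_id!r} missing from partition")
        elif cs.scheme == "gene_window":
            contig_feats = genome.contig_features(feat.contig)
            idx = contig_feats.index(feat)
            lo, hi = max(0, idx - cs.k_genes), idx + cs.k_genes + 1
            grouping = ContextGrouping(sp, feat.contig, contig_feats[lo:hi])
        elif cs.scheme == "nt_window":
            lo, hi = feat.start - cs.window_nt, feat.end + cs.window_nt
            genes = [
                g for g in genome.contig_features(feat.contig)
                if g.end >= lo and g.start <= hi
            ]
            grouping = ContextGrouping(sp, feat.contig, genes)
        else:  # pragma: no cover - ContextSet validates schemes
            raise UsageError(f"unhandled scheme {cs.scheme!r}")

        key = (sp, grouping.gene_ids())
        if key in seen_groupings:
            continue
        seen_groupings[key] = True
        grouping = ContextGrouping(
            sp, grouping.contig, list(grouping.genes),
            leaf_name=name_leaf(sp, serial),
        )
        leaves.append(grouping)
    return leaves
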
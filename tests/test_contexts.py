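import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contexttree import (
    ContextSet,
    Genome,
    NoMatchesError,
    Query,
    UsageError,
    build_context_leaves,
    group_operons,
    group_strand_distance,
    match_query,
    name_leaf,
)
from conftest import mkgene, random_genome


class TestOperonGrouping:
    def test_gap_within_threshold_chains(self, operon_pair):
        (grp,) = group_operons(operon_pair, 20)
        assert grp.gene_ids() == ("g1", "g2")  # gap = 416-400-1 = 15 <= 20

    def test_strand_switch_breaks(self):
        genome = Genome("spA", [mkgene("g1", 100, 400, "+"), mkgene("g2", 416, 900, "-")])
        groups = group_operons(genome, 20)
        assert [g.gene_ids() for g in groups] == [("g1",), ("g2",)]

    def test_gap_above_threshold_breaks(self):
        genome = Genome("spA", [mkgene("g1", 100, 400), mkgene("g2", 500, 900)])
        groups = group_operons(genome, 20)  # gap = 99 > 20
        assert [g.gene_ids() for g in groups] == [("g1",), ("g2",)]

    def test_transitive_chaining(self):
        genome = Genome("spA", [
            mkgene("g1", 100, 400), mkgene("g2", 451, 800), mkgene("g3", 861, 1200),
        ])  # gaps 50 and 60
        (grp,) = group_strand_distance(genome, 75)
        assert grp.gene_ids() == ("g1", "g2", "g3")
        groups = group_strand_distance(genome, 55)  # second gap 60 > 55
        assert [g.gene_ids() for g in groups] == [("g1", "g2"), ("g3",)]

    def test_overlapping_genes_always_chain(self):
        genome = Genome("spA", [mkgene("g1", 100, 400), mkgene("g2", 350, 900)])
        (grp,) = group_operons(genome, 0)  # negative gap <= 0
        assert grp.gene_ids() == ("g1", "g2")

    def test_contig_boundary_breaks(self):
        genome = Genome("spA", [
            mkgene("g1", 100, 400, contig="c1"), mkgene("g2", 405, 900, contig="c2"),
        ])
        assert len(group_operons(genome, 1000)) == 2

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000), threshold=st.integers(0, 200))
    def test_partition_and_kernel_equivalence(self, seed, threshold):
        """Groupings are an exact partition; operon and strand-distance
        grouping implement one rule."""
        genome = random_genome(np.random.default_rng(seed))
        groups = group_operons(genome, threshold)
        ids = [gid for g in groups for gid in g.gene_ids()]
        assert sorted(ids) == sorted(f.gene_id for f in genome)
        assert len(ids) == len(set(ids))
        assert [g.gene_ids() for g in groups] == [
            g.gene_ids() for g in group_strand_distance(genome, threshold)
        ]

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000),
           thresholds=st.tuples(st.integers(0, 150), st.integers(0, 150)))
    def test_threshold_monotonicity(self, seed, thresholds):
        """Every grouping at a lower threshold nests inside exactly one
        grouping at a higher threshold."""
        t1, t2 = sorted(thresholds)
        genome = random_genome(np.random.default_rng(seed))
        fine = group_operons(genome, t1)
        coarse = group_operons(genome, t2)
        membership = {gid: i for i, g in enumerate(coarse) for gid in g.gene_ids()}
        for g in fine:
            assert len({membership[gid] for gid in g.gene_ids()}) == 1


class TestMatchQuery:
    @pytest.fixture
    def genomes(self):
        return [
            Genome("spA", [
                mkgene("a1", 100, 400, annotation="gamma-glutamyl transpeptidase", cluster=7),
                mkgene("a2", 500, 900, annotation="kinase", cluster=9),
            ]),
            Genome("spB", [
                mkgene("b1", 100, 400, annotation="Transpeptidase domain", cluster=7),
            ]),
        ]

    def test_annotation_substring(self, genomes):
        hits = match_query(genomes, None, Query("annotation_text", "transpeptidase"))
        assert [f.gene_id for _, f in hits] == ["a1", "b1"]  # case folded

    def test_case_sensitive_annotation(self, genomes):
        hits = match_query(
            genomes, None, Query("annotation_text", "transpeptidase", case_sensitive=True)
        )
        assert [f.gene_id for _, f in hits] == ["a1"]

    def test_cluster_id_exact(self, genomes):
        hits = match_query(genomes, None, Query("homology_cluster_id", 7))
        assert [f.gene_id for _, f in hits] == ["a1", "b1"]
        assert not [
            f for _, f in match_query(genomes, None, Query("homology_cluster_id", 8))
        ]

    def test_cluster_query_requires_homology_source(self):
        bare = [Genome("spA", [mkgene("a1", 1, 10)])]
        with pytest.raises(UsageError):
            match_query(bare, None, Query("homology_cluster_id", 7))


class TestLeafNaming:
    def test_species_plus_serial(self):
        assert name_leaf("Klebsiella_oxytoca", 1) == "Klebsiella_oxytoca-1"

    def test_whitespace_sanitized(self):
        assert name_leaf("Klebsiella oxytoca M5a1", 2) == "Klebsiella_oxytoca_M5a1-2"

    def test_serial_must_start_at_one(self):
        with pytest.raises(UsageError):
            name_leaf("spA", 0)


class TestBuildContextLeaves:
    @pytest.fixture
    def genomes(self):
        # spA: query gene inside a tight 3-gene run plus a second, distant hit
        return [Genome("spA", [
            mkgene("g1", 100, 400, cluster=1),
            mkgene("g2", 411, 800, cluster=2),
            mkgene("g3", 816, 1200, cluster=1),
            mkgene("g4", 5000, 5400, cluster=1),
        ])]

    def test_single_gene_one_leaf_per_match(self, genomes):
        leaves = build_context_leaves(
            genomes, None, Query("homology_cluster_id", 1),
            ContextSet("sg", "single_gene"),
        )
        assert [lf.leaf_name for lf in leaves] == ["spA-1", "spA-2", "spA-3"]
        assert all(len(lf.genes) == 1 for lf in leaves)

    def test_operon_grouping_deduplicated(self, genomes):
        leaves = build_context_leaves(
            genomes, None, Query("homology_cluster_id", 1),
            ContextSet("op", "operon", threshold_nt=20),
        )
        # matches g1 and g3 share one operon; g4 is its own grouping
        assert [lf.gene_ids() for lf in leaves] == [("g1", "g2", "g3"), ("g4",)]
        assert [lf.leaf_name for lf in leaves] == ["spA-1", "spA-3"]

    def test_gene_window(self, genomes):
        leaves = build_context_leaves(
            genomes, None, Query("homology_cluster_id", 2),
            ContextSet("w", "gene_window", k_genes=1),
        )
        assert leaves[0].gene_ids() == ("g1", "g2", "g3")

    def test_nt_window_degenerate(self, genomes):
        leaves = build_context_leaves(
            genomes, None, Query("homology_cluster_id", 2),
            ContextSet("w", "nt_window", window_nt=0),
        )
        assert leaves[0].gene_ids() == ("g2",)

    def test_nt_window_pulls_overlapping_neighbors(self, genomes):
        leaves = build_context_leaves(
            genomes, None, Query("homology_cluster_id", 2),
            ContextSet("w", "nt_window", window_nt=20),
        )
        assert leaves[0].gene_ids() == ("g1", "g2", "g3")

    def test_zero_matches_signalled(self, genomes):
        with pytest.raises(NoMatchesError):
            build_context_leaves(
                genomes, None, Query("homology_cluster_id", 99),
                ContextSet("sg", "single_gene"),
            )

    def test_leaf_names_unique_and_stable(self, genomes):
        make = lambda: build_context_leaves(
            genomes, None, Query("homology_cluster_id", 1),
            ContextSet("sg", "single_gene"),
        )
        names1 = [lf.leaf_name for lf in make()]
        names2 = [lf.leaf_name for lf in make()]
        assert names1 == names2 and len(set(names1)) == len(names1)
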
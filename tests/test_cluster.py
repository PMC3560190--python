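import math

import numpy as np
import pytest

from contexttree import (
    DissimilarityMatrix,
    LinkageSpec,
    UsageError,
    cluster,
    generate_tie_block,
    linkage_update,
    select_leaves,
    to_json,
    to_newick,
)
from oracles import clades_equal, mst_edge_weights, scipy_clades, tree_clades

SCIPY_METHODS = {
    "single": "single", "complete": "complete", "average_unweighted": "average",
}


def random_matrix(rng, n):
    """A random symmetric matrix; continuous draws make ties negligible."""
    vals = rng.uniform(0.05, 1.0, size=(n, n))
    m = np.triu(vals, k=1)
    m = m + m.T
    return DissimilarityMatrix([f"L{i}" for i in range(n)], m)


class TestLinkageUpdate:
    def test_single_and_complete(self):
        assert linkage_update("single", [0.2, 0.7], [1, 1]) == 0.2
        assert linkage_update("complete", [0.2, 0.7], [1, 1]) == 0.7

    def test_average_unweighted_is_size_weighted(self):
        assert linkage_update("average_unweighted", [0.3, 0.6], [2, 1]) == pytest.approx(0.4)

    def test_average_weighted_is_member_mean(self):
        assert linkage_update("average_weighted", [0.3, 0.6], [2, 1]) == pytest.approx(0.45)

    def test_unknown_method(self):
        with pytest.raises(UsageError):
            linkage_update("median", [0.1], [1])


class TestBasicTrees:
    def test_two_leaves(self):
        m = DissimilarityMatrix(["A", "B"], np.array([[0, 0.4], [0.4, 0]]))
        t = cluster(m, LinkageSpec("single"))
        assert t.root.band_low == t.root.band_high == 0.4
        assert to_newick(t) == "(A:0.4,B:0.4);"

    def test_three_way_tie_single_root(self):
        t = cluster(generate_tie_block(3, 1.0), LinkageSpec("complete"))
        assert len(t.root.children) == 3
        assert t.root.band_low == t.root.band_high == 1.0
        assert to_newick(t) == "(L1:1,L2:1,L3:1);"

    def test_nested_heights_to_branch_lengths(self):
        m = DissimilarityMatrix(
            ["A", "B", "C"],
            np.array([[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]]),
        )
        t = cluster(m, LinkageSpec("complete"))
        assert to_newick(t) == "((A:0.2,B:0.2):0.3,C:0.5);"

    def test_band_mid_height_mode(self):
        m = DissimilarityMatrix(
            ["A", "B", "C"],
            np.array([[0, 1.0, 1.0], [1.0, 0, 1.2], [1.0, 1.2, 0]]),
        )
        # ties at 1.0 merge all three; band [1.0, 1.2], midpoint 1.1
        t = cluster(m, LinkageSpec("single", tie_epsilon=0.25))
        assert t.root.band_low == pytest.approx(1.0)
        assert t.root.band_high == pytest.approx(1.2)
        assert to_newick(t, height_mode="band_mid") == "(A:1.1,B:1.1,C:1.1);"

    def test_matrix_validation(self):
        with pytest.raises(UsageError):
            DissimilarityMatrix(["A", "B"], np.array([[0, 1.0], [0.5, 0]]))
        with pytest.raises(UsageError):
            DissimilarityMatrix(["A", "B"], np.array([[0.3, 1.0], [1.0, 0]]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("method", sorted(SCIPY_METHODS))
    def test_tie_free_matches_pair_group_oracle(self, method):
        """Without ties the variable-group tree collapses to classical
        binary agglomeration: same clades, same merge heights."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 13))
            M = random_matrix(rng, n)
            t = cluster(M, LinkageSpec(method))
            idx = {nm: i for i, nm in enumerate(M.leaves)}
            assert clades_equal(
                tree_clades(t, idx), scipy_clades(M.values, SCIPY_METHODS[method])
            )

    def test_single_linkage_heights_are_mst_edges(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 13))
            M = random_matrix(rng, n)
            t = cluster(M, LinkageSpec("single"))
            idx = {nm: i for i, nm in enumerate(M.leaves)}
            heights = sorted(h for _, h in tree_clades(t, idx))
            assert heights == pytest.approx(mst_edge_weights(M.values))


class TestTieSemantics:
    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_equidistant_block_merges_at_once(self, k):
        t = cluster(generate_tie_block(k, 0.8), LinkageSpec("average_unweighted"))
        assert len(t.root.children) == k
        assert all(c.is_leaf for c in t.root.children)

    def test_permutation_invariance(self):
        """Permuting the input leaves yields the identical tree — the
        defining property of the variable-group method under ties."""
        rng = np.random.default_rng(11)
        base = np.array([
            [0.0, 0.3, 0.3, 0.9],
            [0.3, 0.0, 0.3, 0.9],
            [0.3, 0.3, 0.0, 0.9],
            [0.9, 0.9, 0.9, 0.0],
        ])
        names = ["A", "B", "C", "D"]
        reference = None
        for _ in range(15):
            p = rng.permutation(4)
            M = DissimilarityMatrix(
                [names[i] for i in p], base[np.ix_(p, p)]
            )
            t = cluster(M, LinkageSpec("complete"))
            idx = {nm: i for i, nm in enumerate(names)}
            clades = sorted(
                (tuple(sorted(fs)), round(h, 12)) for fs, h in tree_clades(t, idx)
            )
            if reference is None:
                reference = clades
            assert clades == reference

    def test_fuzzed_permutation_invariance_with_random_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            n = 7
            # draw from a tiny value set to force many exact ties
            vals = rng.choice([0.2, 0.4, 0.6], size=(n, n))
            m = np.triu(vals, k=1)
            m = m + m.T
            names = [f"L{i}" for i in range(n)]
            idx = {nm: i for i, nm in enumerate(names)}
            reference = None
            for _ in range(6):
                p = rng.permutation(n)
                M = DissimilarityMatrix([names[i] for i in p], m[np.ix_(p, p)])
                t = cluster(M, LinkageSpec("average_unweighted"))
                clades = sorted(
                    (tuple(sorted(fs)), h) for fs, h in tree_clades(t, idx)
                )
                if reference is None:
                    reference = clades
                assert [c for c, _ in clades] == [c for c, _ in reference]
                assert [h for _, h in clades] == pytest.approx(
                    [h for _, h in reference], abs=1e-9
                )

    def test_band_low_not_above_band_high_everywhere(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            vals = rng.choice([0.25, 0.5, 0.75, 1.0], size=(9, 9))
            m = np.triu(vals, k=1)
            m = m + m.T
            M = DissimilarityMatrix([f"L{i}" for i in range(9)], m)
            t = cluster(M, LinkageSpec("complete"))

            def walk(node):
                if node.is_leaf:
                    return
                assert node.band_low <= node.band_high + 1e-12
                for c in node.children:
                    walk(c)

            walk(t.root)


class TestJointBetweenWithin:
    def test_pairwise_rms_by_hand(self):
        """d(U,K) is the RMS leaf-to-leaf dissimilarity over all pairs in
        the union of the two clusters."""
        m = np.array([
            [0.0, 0.1, 0.8, 0.9],
            [0.1, 0.0, 0.7, 0.6],
            [0.8, 0.7, 0.0, 0.2],
            [0.9, 0.6, 0.2, 0.0],
        ])
        M = DissimilarityMatrix(["A", "B", "C", "D"], m)
        t = cluster(M, LinkageSpec("joint_between_within"))
        # first round merges {A,B} at 0.1 and {C,D} at 0.2 (tie-free minima
        # chosen sequentially); root distance is RMS over all six pairs
        expected_root = math.sqrt(
            (0.1**2 + 0.8**2 + 0.9**2 + 0.7**2 + 0.6**2 + 0.2**2) / 6
        )
        assert t.root.band_low == pytest.approx(expected_root)
        leaf_sets = sorted(
            tuple(sorted(c.leaf_names())) for c in t.root.children
        )
        assert leaf_sets == [("A", "B"), ("C", "D")]

    def test_member_update_route_rejected(self):
        with pytest.raises(UsageError):
            linkage_update("joint_between_within", [0.1], [1])


class TestTreeUtilities:
    @pytest.fixture
    def tree(self):
        m = DissimilarityMatrix(
            ["Klebsiella_oxytoca-1", "Ecoli-1", "Ecoli-2"],
            np.array([[0, 0.9, 0.9], [0.9, 0, 0.1], [0.9, 0.1, 0]]),
        )
        return cluster(m, LinkageSpec("complete"))

    def test_leaf_conservation(self, tree):
        assert sorted(tree.leaf_names()) == ["Ecoli-1", "Ecoli-2", "Klebsiella_oxytoca-1"]

    def test_select_leaves_substring(self, tree):
        assert select_leaves(tree, "oxytoca") == ["Klebsiella_oxytoca-1"]
        assert select_leaves(tree, "ECOLI") == ["Ecoli-1", "Ecoli-2"]
        assert select_leaves(tree, "") == tree.leaf_names()
        assert select_leaves(tree, "zzz") == []

    def test_newick_quotes_unsafe_names(self):
        m = DissimilarityMatrix(
            ["sp (x)-1", "spB-1"], np.array([[0, 0.5], [0.5, 0]])
        )
        t = cluster(m, LinkageSpec("single"))
        assert to_newick(t) == "('sp (x)-1':0.5,spB-1:0.5);"

    def test_json_dump_carries_bands(self, tree):
        import json

        data = json.loads(to_json(tree))
        assert data["linkage"] == "complete"
        assert data["tree"]["band_low"] == pytest.approx(0.9)
        assert {"leaf": "Klebsiella_oxytoca-1"} in data["tree"]["children"]
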
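"""Dendrogram builders, Newick serialization, and tree evaluation."""

import itertools

import numpy as np
import pytest

from propseq.alignment import PropertyWave
from propseq.distances import DistanceMatrix, pairwise_distances
from propseq.exceptions import PropseqError
from propseq.phylo import (
    Dendrogram,
    Node,
    is_monophyletic,
    ranking_match,
    ranking_report,
    stat_merge_tree,
    string_merge_tree,
    to_newick,
    upgma,
)
from propseq.simstats import PairStatTable
from propseq.simulate import random_tree


def dm3():
    return DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))


class TestUPGMA:
    def test_three_leaf_hand_agglomeration(self):
        assert to_newick(upgma(dm3())) == "((A:1,B:1):1,C:2);"

    def test_two_leaf_merge_at_half_distance(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 6], [6, 0]], float))
        assert to_newick(upgma(dm)) == "(A:3,B:3);"

    def test_ultrametric_input_reproduced_cophenetically(self):
        for seed in range(5):
            true = random_tree(7, seed)
            coph = true.cophenetic_matrix()
            rebuilt = upgma(coph)
            assert np.allclose(rebuilt.cophenetic_matrix().d, coph.d)

    def test_cross_check_against_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        n = 8
        d = np.abs(rng.standard_normal((n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(tuple(f"t{i}" for i in range(n)), d)
        ours = upgma(dm).cophenetic_matrix()
        theirs = squareform(cophenet(linkage(squareform(d), method="average")))
        # scipy orders taxa t0..t{n-1}; ours sorts labels, same order here for n<=9
        assert np.allclose(ours.d, theirs)

    def test_wpgma_cross_check_against_scipy(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        n = 7
        d = np.abs(rng.standard_normal((n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(tuple(f"t{i}" for i in range(n)), d)
        ours = upgma(dm, weighting="weighted").cophenetic_matrix()
        theirs = squareform(cophenet(linkage(squareform(d), method="weighted")))
        assert np.allclose(ours.d, theirs)

    def test_taxon_permutation_invariance(self, rng):
        n = 6
        d = np.abs(rng.standard_normal((n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        taxa = tuple(f"t{i}" for i in range(n))
        base = upgma(DistanceMatrix(taxa, d))
        perm = rng.permutation(n)
        permuted = upgma(DistanceMatrix(tuple(taxa[i] for i in perm), d[np.ix_(perm, perm)]))
        assert to_newick(base) == to_newick(permuted)

    def test_rejects_bad_weighting(self):
        with pytest.raises(PropseqError):
            upgma(dm3(), weighting="median")


class TestStringMergeTree:
    def test_hand_iteration(self):
        waves = [
            PropertyWave("a", "p", [0, 0]),
            PropertyWave("b", "p", [2, 2]),
            PropertyWave("c", "p", [8, 8]),
        ]
        # first merge {a,b} at sum-difference 4 (height 2); merged string [1,1];
        # final merge vs [8,8] at sum-difference 14 (height 7)
        assert to_newick(string_merge_tree(waves)) == "((a:2,b:2):5,c:7);"

    def test_identical_pair_merges_at_zero(self):
        waves = [PropertyWave("a", "p", [1, 2]), PropertyWave("b", "p", [1, 2])]
        assert string_merge_tree(waves).root.height == 0.0

    def test_all_identical_ties_resolved_lexicographically(self):
        waves = [PropertyWave(n, "p", [1.0, 1.0]) for n in ("c", "a", "b")]
        tree = string_merge_tree(waves)
        assert tree.root.height == 0.0
        assert tree.leaf_names == ("a", "b", "c")

    def test_ultrametric_sum_differences_match_upgma_topology(self):
        waves = [
            PropertyWave("a", "p", [0.0, 0.0]),
            PropertyWave("b", "p", [1.0, 1.0]),
            PropertyWave("c", "p", [10.0, 10.0]),
            PropertyWave("d", "p", [11.0, 11.0]),
        ]
        dm = pairwise_distances(waves, "sum_difference")
        assert string_merge_tree(waves).clades() == upgma(dm).clades()


class TestStatMergeTree:
    def test_two_taxa(self):
        t = PairStatTable(("a", "b"), "s", np.array([[1.0, 0.5], [0.5, 1.0]]))
        tree = stat_merge_tree(t)
        assert tree.leaf_names == ("a", "b")
        assert tree.root.height == 1.0  # distance 1/0.5 = 2, merged at 1

    def test_three_taxa_topology_matches_upgma_case(self):
        # transformed distances: AB=2, AC=BC=4
        vals = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.25], [0.25, 0.25, 1.0]])
        tree = stat_merge_tree(PairStatTable(("A", "B", "C"), "s", vals))
        assert to_newick(tree) == "((A:1,B:1):1,C:2);"

    def test_equal_statistics_deterministic(self):
        vals = np.full((3, 3), 0.5)
        t1 = stat_merge_tree(PairStatTable(("x", "y", "z"), "s", vals))
        t2 = stat_merge_tree(PairStatTable(("z", "x", "y"), "s", vals))
        assert to_newick(t1) == to_newick(t2)


class TestNewick:
    def test_three_leaf_example(self):
        assert to_newick(upgma(dm3())) == "((A:1,B:1):1,C:2);"

    def test_single_leaf(self):
        assert to_newick(Dendrogram(Node(0.0, name="A"))) == "A;"

    def test_round_trip_through_own_reader(self):
        from propseq.phylo import from_newick

        tree = upgma(dm3())
        back = from_newick(to_newick(tree))
        assert back.leaf_names == tree.leaf_names
        assert np.allclose(back.cophenetic_matrix().d, tree.cophenetic_matrix().d)
        assert to_newick(from_newick("A;")) == "A;"

    def test_round_trip_through_skbio(self):
        skbio = pytest.importorskip("skbio")
        import io

        tree = upgma(dm3())
        parsed = skbio.TreeNode.read(io.StringIO(to_newick(tree)))
        tips = {t.name: parsed.distance(t) for t in parsed.tips()}
        coph = tree.cophenetic_matrix()
        root_height = tree.root.height
        for name, depth in tips.items():
            assert depth == pytest.approx(root_height)
        assert parsed.distance(parsed.find("A"), parsed.find("B")) == pytest.approx(
            coph.value("A", "B")
        )


def _achievable_orders(node):
    """Brute-force planar rotations: all leaf orders reachable by child flips."""
    if node.is_leaf:
        return [(node.name,)]
    left, right = node.children
    orders = []
    for lo in _achievable_orders(left):
        for ro in _achievable_orders(right):
            orders.append(lo + ro)
            orders.append(ro + lo)
    return orders


class TestEvaluation:
    def test_monophyly(self):
        tree = upgma(dm3())
        assert is_monophyletic(tree, {"A", "B"})
        assert not is_monophyletic(tree, {"A", "C"})
        assert is_monophyletic(tree, {"A", "B", "C"})

    def test_monophyly_unknown_label(self):
        with pytest.raises(PropseqError):
            is_monophyletic(upgma(dm3()), {"A", "Z"})

    def test_ranking_examples(self):
        tree = upgma(dm3())
        assert ranking_match(tree, ["A", "B", "C"]) == 1
        assert ranking_match(tree, ["A", "C", "B"]) == 0
        assert ranking_match(tree, [{"A", "B", "C"}]) == 1

    def test_ranking_against_exhaustive_rotation_oracle(self):
        for seed in range(6):
            tree = random_tree(6, seed)
            orders = set(_achievable_orders(tree.root))
            leaves = list(tree.leaf_names)
            rng = np.random.default_rng(seed)
            for _ in range(20):
                candidate = tuple(rng.permutation(leaves))
                assert ranking_match(tree, list(candidate)) == int(candidate in orders)

    def test_ranking_with_groups(self):
        tree = upgma(
            DistanceMatrix(
                ("A", "B", "C", "D"),
                np.array(
                    [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float
                ),
            )
        )
        assert ranking_match(tree, [{"A", "B"}, {"C", "D"}]) == 1
        assert ranking_match(tree, [{"A", "C"}, {"B", "D"}]) == 0

    def test_ranking_report_layout(self):
        trees = {"t1": upgma(dm3())}
        report = ranking_report(trees, ["A", "B", "C"])
        assert report.loc["t1", "match"] == 1
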
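import numpy as np
import pandas as pd
import pytest

import kmerscape as km
from kmerscape.lca_taxonomy import TaxonomyTable
from kmerscape.similarity import SimilarityMatrix
from kmerscape.tree_analysis import (
    ClusterTree,
    adjacent_leaf_objective,
    from_newick,
    generalized_rf,
    optimal_leaf_order,
    random_tree,
    reference_tree,
    similarity_to_dissimilarity,
    to_newick,
    ward_cluster,
)

# 12-point dissimilarity matrix (Euclidean distances of 12 random planar
# points, rounded to 6 decimals) together with the merge heights produced by
# R's hclust(method = "ward.D2") on the same matrix -- an independent
# reference implementation of the Ward.D2 criterion.
R_WARD_D12 = np.array([
    [0.0, 0.321134, 0.318308, 0.670004, 0.070781, 0.70249, 0.745325, 0.405499, 0.439949, 0.516734, 0.069238, 0.56847],
    [0.321134, 0.0, 0.43484, 0.547987, 0.374543, 0.803977, 0.572566, 0.487904, 0.607623, 0.354796, 0.314959, 0.324182],
    [0.318308, 0.43484, 0.0, 0.431884, 0.374827, 0.394064, 0.538703, 0.088273, 0.174199, 0.756451, 0.38544, 0.75641],
    [0.670004, 0.547987, 0.431884, 0.0, 0.739962, 0.494304, 0.123186, 0.373456, 0.518524, 0.893293, 0.718916, 0.820856],
    [0.070781, 0.374543, 0.374827, 0.739962, 0.0, 0.748756, 0.816089, 0.462997, 0.479401, 0.524478, 0.066084, 0.592596],
    [0.70249, 0.803977, 0.394064, 0.494304, 0.748756, 0.0, 0.613619, 0.320068, 0.275284, 1.143651, 0.77149, 1.127655],
    [0.745325, 0.572566, 0.538703, 0.123186, 0.816089, 0.613619, 0.0, 0.488386, 0.638152, 0.898711, 0.787062, 0.809176],
    [0.405499, 0.487904, 0.088273, 0.373456, 0.462997, 0.320068, 0.488386, 0.0, 0.16042, 0.823639, 0.471893, 0.812065],
    [0.439949, 0.607623, 0.174199, 0.518524, 0.479401, 0.275284, 0.638152, 0.16042, 0.0, 0.918672, 0.509072, 0.92711],
    [0.516734, 0.354796, 0.756451, 0.893293, 0.524478, 1.143651, 0.898711, 0.823639, 0.918672, 0.0, 0.462578, 0.143769],
    [0.069238, 0.314959, 0.38544, 0.718916, 0.066084, 0.77149, 0.787062, 0.471893, 0.509072, 0.462578, 0.0, 0.52694],
    [0.56847, 0.324182, 0.75641, 0.820856, 0.592596, 1.127655, 0.809176, 0.812065, 0.92711, 0.143769, 0.52694, 0.0],
])
R_WARD_HEIGHTS = [
    0.066084, 0.07127553614, 0.088273, 0.123186, 0.143769, 0.18651864382,
    0.38352697259, 0.39510794592, 0.77133165451, 0.80055056445, 1.50374866689,
]
# R merge list, converted to 0-based leaf indices per merge step
R_WARD_MERGES = [
    {4, 10}, {0, 4, 10}, {2, 7}, {3, 6}, {9, 11}, {2, 7, 8},
    {1, 9, 11}, {2, 5, 7, 8}, {0, 1, 4, 9, 10, 11},
    {2, 3, 5, 6, 7, 8}, set(range(12)),
]


def flip_orders(Z, n):
    """All leaf orders reachable by flipping internal nodes (exhaustive)."""
    def rec(node):
        if node < n:
            return [[node]]
        a, b, _, _ = Z[int(node) - n]
        la, lb = rec(int(a)), rec(int(b))
        return [x + y for x in la for y in lb] + [y + x for x in la for y in lb]
    return rec(2 * n - 2)


class TestWardCluster:
    def test_two_leaves_merge_at_their_distance(self):
        D = np.array([[0.0, 0.6], [0.6, 0.0]])
        t = ward_cluster(D, ["a", "b"])
        assert t.heights[0] == pytest.approx(0.6)

    def test_three_equidistant_leaves(self):
        D = np.ones((3, 3)) - np.eye(3)
        t = ward_cluster(D)
        merged = t.clusters()
        assert merged[0] == frozenset({"L0", "L1"})  # lowest-index tie rule
        assert t.heights[1] >= t.heights[0]

    def test_matches_r_ward_d2_reference(self):
        """Merge heights and merge composition agree digit-for-digit with
        R hclust ward.D2 on the frozen 12-point matrix."""
        t = ward_cluster(R_WARD_D12)
        assert np.allclose(t.heights, R_WARD_HEIGHTS, atol=1e-9)
        clusters = [
            {int(lab[1:]) for lab in clade} for clade in t.clusters()
        ]
        assert clusters == R_WARD_MERGES

    def test_heights_nondecreasing(self, rng):
        X = rng.random((15, 4))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        np.fill_diagonal(D, 0)
        t = ward_cluster(D)
        assert np.all(np.diff(t.heights) >= -1e-12)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            ward_cluster(np.array([[0.0, -1.0], [-1.0, 0.0]]))  # negative


class TestOptimalLeafOrder:
    def test_two_leaves_deterministic(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        t = optimal_leaf_order(ward_cluster(D, ["a", "b"]), D)
        assert t.leaf_order == ["a", "b"]

    def test_matches_exhaustive_search_small_instances(self, rng):
        """DP optimum equals brute force over all 2^(n-1) flips for n <= 8."""
        for trial in range(12):
            n = int(rng.integers(4, 9))
            X = rng.random((n, 3))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            np.fill_diagonal(D, 0)
            t = ward_cluster(D)
            opt = optimal_leaf_order(t, D)
            obj = adjacent_leaf_objective(opt.leaf_order, D, opt.labels)
            best = min(
                sum(D[o[i], o[i + 1]] for i in range(n - 1))
                for o in flip_orders(t.linkage, n)
            )
            assert obj == pytest.approx(best, abs=1e-12)

    def test_never_worse_than_input_embedding(self, rng):
        X = rng.random((12, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        np.fill_diagonal(D, 0)
        t = ward_cluster(D)
        before = adjacent_leaf_objective(t.leaf_order, D, t.labels)
        after_t = optimal_leaf_order(t, D)
        after = adjacent_leaf_objective(after_t.leaf_order, D, after_t.labels)
        assert after <= before + 1e-12

    def test_chain_recovers_line_order(self, rng):
        xs = np.sort(rng.random(10))
        D = np.abs(xs[:, None] - xs[None, :])
        t = optimal_leaf_order(ward_cluster(D), D)
        idx = [int(lab[1:]) for lab in t.leaf_order]
        assert idx == list(range(10)) or idx == list(range(9, -1, -1))

    def test_label_mismatch_rejected(self):
        D3 = np.ones((3, 3)) - np.eye(3)
        t = ward_cluster(D3)
        with pytest.raises(ValueError):
            optimal_leaf_order(t, np.zeros((4, 4)))


class TestSimilarityToDissimilarity:
    def make(self, J):
        n = J.shape[0]
        return SimilarityMatrix([f"g{i}" for i in range(n)], 21, J)

    def test_one_minus(self):
        J = np.array([[1.0, 0.4], [0.4, 1.0]])
        D = similarity_to_dissimilarity(self.make(J), "one-minus")
        assert D[0, 1] == pytest.approx(0.6)
        assert D[0, 0] == 0.0

    def test_neglog_zero_diagonal_and_monotone(self):
        J = np.array([[1.0, 0.4, 0.1], [0.4, 1.0, 0.2], [0.1, 0.2, 1.0]])
        D = similarity_to_dissimilarity(self.make(J), "neglog")
        assert np.allclose(np.diag(D), 0.0)
        # J order reversed: larger similarity -> smaller dissimilarity
        assert D[0, 1] < D[1, 2] < D[0, 2]

    def test_unknown_mode_rejected(self, small_clade_similarity):
        with pytest.raises(ValueError):
            similarity_to_dissimilarity(small_clade_similarity, "exp")


class TestReferenceTree:
    def test_two_genera_in_one_family(self):
        df = pd.DataFrame(
            {
                "genome_id": ["a", "b", "c", "d"],
                "species": ["s1", "s2", "s3", "s4"],
                "genus": ["g1", "g1", "g2", "g2"],
                "family": ["f1"] * 4,
                "superkingdom": ["Bacteria"] * 4,
            }
        )
        tree = reference_tree(TaxonomyTable(df))
        assert generalized_rf(tree, "((a,b),(c,d));") == pytest.approx(0.0, abs=1e-9)

    def test_missing_rank_attaches_at_parent(self):
        df = pd.DataFrame(
            {
                "genome_id": ["a", "b", "c"],
                "genus": ["g1", "g1", None],
                "family": ["f1", "f1", "f1"],
                "superkingdom": ["B"] * 3,
            }
        )
        newick = to_newick(reference_tree(TaxonomyTable(df)))
        # c has no genus: sits beside the g1 clade, not inside it
        assert "(a,b)g1" in newick.replace("'", "")

    def test_simulated_taxonomy_reproduces_truth(self, small_clade):
        spec, _, taxonomy, truth = small_clade
        ref = reference_tree(taxonomy, ranks=spec.ranks)
        assert generalized_rf(ref, truth) == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame(
            {"genome_id": ["a", "a"], "superkingdom": ["B", "B"]}
        )
        with pytest.raises(ValueError):
            reference_tree(df)


class TestGeneralizedRF:
    def test_identical_trees_zero(self, rng):
        t = random_tree(12, rng)
        assert generalized_rf(t, t) == pytest.approx(0.0, abs=1e-12)

    def test_swap_across_root_is_positive(self):
        t1 = "(((a,b),(c,d)),((e,f),(g,h)));"
        t2 = "(((a,f),(c,d)),((e,b),(g,h)));"
        d = generalized_rf(t1, t2)
        assert 0.0 < d <= 1.0

    def test_symmetry(self, rng):
        t1, t2 = random_tree(10, rng), random_tree(10, rng)
        assert generalized_rf(t1, t2) == pytest.approx(generalized_rf(t2, t1))

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generalized_rf("((a,b),(c,d));", "((a,b),(c,e));")

    def test_polytomous_reference_accepted(self):
        d = generalized_rf("((a,b),(c,d),(e,f));", "(((a,b),(c,d)),(e,f));")
        assert 0.0 <= d < 0.5


class TestRandomTree:
    def test_minimum_size(self, rng):
        t = random_tree(2, rng)
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["t1", "t2"]
        with pytest.raises(ValueError):
            random_tree(1, rng)

    def test_seeded_reproducibility(self):
        a = to_newick(random_tree(9, np.random.default_rng(5)))
        b = to_newick(random_tree(9, np.random.default_rng(5)))
        assert a == b

    def test_all_five_leaf_topologies_reachable(self):
        """With 5 leaves there are 15 unrooted binary topologies; a long run
        of draws should visit every one of them."""
        rng = np.random.default_rng(31)
        seen = set()
        for _ in range(600):
            t = random_tree(5, rng)
            # canonical signature: the set of nontrivial splits as sorted labels
            from kmerscape.tree_analysis import _leaf_set, _split_masks

            taxa = _leaf_set(t)
            seen.add(tuple(_split_masks(t, taxa)))
        assert len(seen) == 15


class TestNewickIO:
    def test_round_trip_topology(self, rng):
        t = random_tree(8, rng)
        back = from_newick(to_newick(t))
        assert generalized_rf(t, back) == pytest.approx(0.0, abs=1e-12)

    def test_polytomy_preserved(self):
        t = from_newick("(a,b,c);")
        root_children = len(t.seed_node.child_nodes())
        assert root_children == 3

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            from_newick("((a,b),(c,d);")

    def test_cluster_tree_newick_has_heights(self):
        D = np.array([[0.0, 0.4, 1.0], [0.4, 0.0, 1.0], [1.0, 1.0, 0.0]])
        t = ward_cluster(D, ["x", "y", "z"])
        nwk = t.to_newick()
        assert nwk.endswith(";") and ":" in nwk
        parsed = from_newick(nwk)
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == ["x", "y", "z"]


def test_clustering_recovers_simulated_topology(small_clade, small_clade_similarity):
    """Ward.D2 on 1 - J over the simulated clade reproduces the true
    topology exactly (generalized RF distance 0)."""
    _, _, _, truth = small_clade
    D = similarity_to_dissimilarity(small_clade_similarity)
    tree = ward_cluster(D, small_clade_similarity.genome_ids)
    assert generalized_rf(tree, truth) == pytest.approx(0.0, abs=1e-9)
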
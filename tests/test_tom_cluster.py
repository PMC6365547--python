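"""Topological overlap and deterministic hierarchical clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

import oracles
from skullnet.net_model import AnatomicalNetwork
from skullnet.synthetic import SyntheticSpec, fixture, generate_bilateral_skull
from skullnet.tom_cluster import (
    MergeTree,
    hierarchical_cluster,
    to_dissimilarity,
    topological_overlap,
)


class TestTopologicalOverlap:
    def test_identical_neighbor_sets_give_one(self):
        # a and b both connect exactly to {c, d}
        net = AnatomicalNetwork.from_edges(
            "abcd", [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]
        )
        assert topological_overlap(net).loc("a", "b") == 1.0

    def test_disjoint_neighborhoods_give_zero(self, path3):
        # in a-b-c, the ends share b; extend so two nodes share nothing
        net = AnatomicalNetwork.from_edges(
            "abcd", [("a", "b"), ("c", "d")]
        )
        assert topological_overlap(net).loc("a", "c") == 0.0

    def test_adjacent_triangle_pair_is_half(self, triangle):
        assert topological_overlap(triangle).loc("a", "b") == 0.5

    def test_isolated_node_rows_are_zero(self):
        net = AnatomicalNetwork.from_edges("abc", [("a", "b")])
        tom = topological_overlap(net)
        assert tom.loc("a", "c") == 0.0 and tom.loc("b", "c") == 0.0

    def test_adjacency_corrected_variant_rewards_direct_links(self, triangle):
        plain = topological_overlap(triangle).loc("a", "b")
        corrected = topological_overlap(
            triangle, adjacency_correction=True
        ).loc("a", "b")
        assert corrected == pytest.approx((1 + 1) / (2 + 1 - 1)) == 1.0
        assert corrected > plain

    def test_two_step_neighborhoods_widen_overlap(self, path3):
        # ends of a path share no 1-step neighbors' count change at m=2
        net = AnatomicalNetwork.from_edges(
            "abcde", [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        )
        m1 = topological_overlap(net, m=1).loc("a", "e")
        m2 = topological_overlap(net, m=2).loc("b", "d")
        assert m1 == 0.0
        assert m2 > 0.0

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_set_intersection_oracle(self, seed):
        net = oracles.random_network(seed)
        tom = topological_overlap(net)
        expected = oracles.topological_overlap(net)
        for (a, b), val in expected.items():
            assert tom.loc(a, b) == pytest.approx(val)

    def test_mirrored_pairs_have_equal_overlap(self):
        spec = SyntheticSpec(
            block_sizes=(4, 4),
            bilateral=True,
            midline=(("b1n1", "b1n1"),),
            seed=11,
        )
        net, _ = generate_bilateral_skull(spec)
        tom = topological_overlap(net)
        half = [l[2:] for l in net.labels if l.startswith("L_")]
        for x in half:
            for y in half:
                if x < y:
                    assert tom.loc(f"L_{x}", f"L_{y}") == pytest.approx(
                        tom.loc(f"R_{x}", f"R_{y}")
                    )


class TestDissimilarity:
    def test_extremes_and_triangle_value(self, triangle):
        dis = to_dissimilarity(topological_overlap(triangle))
        assert dis.loc["a", "b"] == pytest.approx(0.5)
        assert np.allclose(np.diag(dis.to_numpy()), 0.0)

    def test_to_one_maps_to_distance_zero(self):
        net = AnatomicalNetwork.from_edges(
            "abcd", [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]
        )
        dis = to_dissimilarity(topological_overlap(net))
        assert dis.loc["a", "b"] == 0.0


class TestHierarchicalCluster:
    def test_within_triangle_pairs_merge_before_cross(self, two_triangle):
        tree = hierarchical_cluster(
            to_dissimilarity(topological_overlap(two_triangle))
        )
        # the penultimate state must be exactly the two triangles
        clusters = tree.cut(tree.merges[-1][2])
        assert set(clusters) == {
            frozenset("abc"),
            frozenset("def"),
        }

    def test_distance_zero_pair_merges_first_at_height_zero(self):
        net = AnatomicalNetwork.from_edges(
            "abcd", [("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")]
        )
        tree = hierarchical_cluster(to_dissimilarity(topological_overlap(net)))
        left, right, h = tree.merges[0]
        assert h == 0.0
        assert {tree.labels[left], tree.labels[right]} == {"a", "b"}

    def test_label_permutation_gives_isomorphic_tree(self, two_triangle):
        dis = to_dissimilarity(topological_overlap(two_triangle))
        perm = list(reversed(dis.columns))
        tree1 = hierarchical_cluster(dis)
        tree2 = hierarchical_cluster(dis.loc[perm, perm])
        h1 = sorted(h for _, _, h in tree1.merges)
        h2 = sorted(h for _, _, h in tree2.merges)
        assert h1 == pytest.approx(h2)
        clusters1 = {frozenset(m) for _, m, _ in tree1.internal_nodes()}
        clusters2 = {frozenset(m) for _, m, _ in tree2.internal_nodes()}
        assert clusters1 == clusters2

    def test_rejects_asymmetric_input(self):
        bad = pd.DataFrame(
            [[0.0, 0.2], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValueError):
            hierarchical_cluster(bad)

    @pytest.mark.parametrize("seed", range(10))
    def test_average_heights_equal_mean_cross_dissimilarity(self, seed):
        net = oracles.random_network(seed, n_max=15)
        dis = to_dissimilarity(topological_overlap(net))
        tree = hierarchical_cluster(dis)
        for left, right, h in tree.merges:
            a = sorted(tree.members(left))
            b = sorted(tree.members(right))
            assert h == pytest.approx(dis.loc[a, b].to_numpy().mean())

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_merge_heights_match_scipy_on_tie_free_input(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 10))
        # continuous draws: derived average distances almost surely tie-free
        condensed = rng.uniform(0.05, 1.0, size=n * (n - 1) // 2)
        labels = [f"x{i}" for i in range(n)]
        dis = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
        for linkage in ("average", "single", "complete"):
            ours = sorted(h for _, _, h in hierarchical_cluster(dis, linkage).merges)
            ref = sorted(hierarchy.linkage(condensed, method=linkage)[:, 2])
            assert ours == pytest.approx(ref)


class TestMergeTreeExports:
    def test_merge_table_shape_and_monotone_heights(self, two_triangle):
        tree = hierarchical_cluster(
            to_dissimilarity(topological_overlap(two_triangle))
        )
        table = tree.merge_table()
        assert list(table.columns) == ["step", "child1", "child2", "height"]
        assert len(table) == two_triangle.n - 1
        assert table["height"].is_monotonic_increasing

    def test_newick_is_parseable_and_ultrametric(self, two_triangle):
        import dendropy

        tree = hierarchical_cluster(
            to_dissimilarity(topological_overlap(two_triangle))
        )
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        leaves = {l.taxon.label for l in parsed.leaf_node_iter()}
        assert leaves == set(two_triangle.labels)
        root_height = tree.merges[-1][2]
        for leaf in parsed.leaf_node_iter():
            assert leaf.distance_from_root() == pytest.approx(root_height)
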
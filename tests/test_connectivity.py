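"""Dispersal kernel, max-product path probabilities, PC and dPC."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from aguadanet.connectivity import (
    aggregate_importance,
    assign_link_probabilities,
    calibrate_kernel,
    max_product_paths,
    node_importance,
    pc_numerator,
)
from aguadanet.errors import ValidationError
from aguadanet.network import build_complete_network, prune_by_distance

from conftest import make_table, random_table


def brute_force_pairs(net):
    """Independent p* oracle: exhaustive simple-path enumeration (networkx)."""
    g = nx.Graph()
    g.add_nodes_from(net.nodes.ids)
    for l in net.links:
        g.add_edge(l.a, l.b, p=l.probability)
    n = len(net.nodes)
    mat = np.eye(n)
    ids = net.nodes.ids
    for i, j in itertools.combinations(range(n), 2):
        best = 0.0
        for path in nx.all_simple_paths(g, ids[i], ids[j]):
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= g.edges[a, b]["p"]
            best = max(best, prod)
        mat[i, j] = mat[j, i] = best
    return mat


def pruned_random_net(rng, n, d=6_000.0, extent=15_000.0):
    table = random_table(rng, n, extent=extent)
    net = prune_by_distance(build_complete_network(table), d)
    return assign_link_probabilities(net, calibrate_kernel(d))


class TestKernel:
    @pytest.mark.parametrize("d_max", [2_240.0, 3_000.0, 13_000.0, 16_000.0])
    def test_tail_probability_at_d_max(self, d_max):
        k = calibrate_kernel(d_max)
        assert k.probability(d_max) == pytest.approx(0.05, rel=1e-12)
        assert k.probability(0.0) == 1.0

    def test_closed_form_decay_rate(self):
        k = calibrate_kernel(13_000.0)
        assert k.decay_rate == pytest.approx(2.30436e-4, rel=1e-4)
        assert k.probability(6_500.0) == pytest.approx(math.sqrt(0.05), rel=1e-12)

    @pytest.mark.parametrize("bad", [(0.0, 0.05), (-1.0, 0.05), (1.0, 0.0), (1.0, 1.0)])
    def test_invalid_calibration_rejected(self, bad):
        with pytest.raises(ValidationError):
            calibrate_kernel(*bad)


class TestLinkProbabilities:
    def test_boundary_values(self):
        table = make_table([("a", 0, 0, 1), ("b", 0, 0, 1), ("c", 5_000, 0, 1)])
        net = build_complete_network(table)
        net = prune_by_distance(net, 5_000.0)
        net = assign_link_probabilities(net, calibrate_kernel(5_000.0))
        probs = {frozenset((l.a, l.b)): l.probability for l in net.links}
        assert probs[frozenset("ab")] == pytest.approx(1.0)  # zero length
        assert probs[frozenset("ac")] == pytest.approx(0.05)  # length = d_max

    def test_matches_direct_exponential(self, rng):
        net = pruned_random_net(rng, 20)
        kernel = calibrate_kernel(6_000.0)
        for l in net.links:
            assert l.probability == pytest.approx(
                math.exp(-kernel.decay_rate * l.length), abs=1e-12
            )

    def test_unpruned_network_rejected(self, tiny_table):
        net = build_complete_network(tiny_table)  # has a 9 km link
        with pytest.raises(ValidationError, match="prune"):
            assign_link_probabilities(net, calibrate_kernel(5_000.0))


class TestMaxProductPaths:
    def test_two_link_chain(self):
        # chain a-b-c; a-c has no direct link after pruning
        d = -math.log(0.9) / calibrate_kernel(1.0).decay_rate  # length with p=0.9
        table = make_table([("a", 0, 0, 1), ("b", d, 0, 1), ("c", 2 * d, 0, 1)])
        net = prune_by_distance(build_complete_network(table), d)
        net = assign_link_probabilities(net, calibrate_kernel(1.0))
        pairs = max_product_paths(net)
        i, j = pairs.ids.index("a"), pairs.ids.index("c")
        assert pairs.matrix[i, j] == pytest.approx(0.81, rel=1e-12)

    def test_disconnected_pair_is_zero(self):
        table = make_table([("a", 0, 0, 1), ("b", 100, 0, 1), ("c", 99_999, 0, 1)])
        net = prune_by_distance(build_complete_network(table), 200.0)
        net = assign_link_probabilities(net, calibrate_kernel(200.0))
        m = max_product_paths(net).matrix
        assert m[0, 2] == 0.0 and m[1, 2] == 0.0
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            net = pruned_random_net(rng, int(rng.integers(2, 9)))
            got = max_product_paths(net).matrix
            np.testing.assert_allclose(got, brute_force_pairs(net), atol=1e-12)

    def test_euclidean_kernel_identity(self, rng):
        """exp(-k d) multiplicative over lengths => p* = exp(-k * graph distance)."""
        for _ in range(10):
            table = random_table(rng, 25)
            net = prune_by_distance(build_complete_network(table), 5_000.0)
            kernel = calibrate_kernel(5_000.0)
            net = assign_link_probabilities(net, kernel)
            got = max_product_paths(net).matrix
            g = nx.Graph()
            g.add_nodes_from(range(25))
            for k in range(net.n_links):
                i, j = net.edges[k]
                g.add_edge(int(i), int(j), w=float(net.lengths[k]))
            expected = np.zeros((25, 25))
            for i, dists in nx.all_pairs_dijkstra_path_length(g, weight="w"):
                for j, d in dists.items():
                    expected[i, j] = math.exp(-kernel.decay_rate * d)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_component_mode_is_indicator(self, rng):
        net = pruned_random_net(rng, 15, d=3_000.0, extent=20_000.0)
        m = max_product_paths(net, mode="component").matrix
        assert set(np.unique(m)) <= {0.0, 1.0}
        mp = max_product_paths(net).matrix
        assert np.array_equal(m > 0, mp > 0)  # same reachability structure


class TestPcNumerator:
    def test_hand_computed_examples(self):
        one = make_table([("a", 0, 0, 2.0)])
        net = assign_link_probabilities(
            build_complete_network(one), calibrate_kernel(1.0)
        )
        assert pc_numerator(max_product_paths(net), one.areas) == pytest.approx(4.0)

        two = make_table([("a", 0, 0, 2.0), ("b", 10_000, 0, 3.0)])
        net = prune_by_distance(build_complete_network(two), 100.0)
        net = assign_link_probabilities(net, calibrate_kernel(100.0))
        assert pc_numerator(max_product_paths(net), two.areas) == pytest.approx(13.0)

        # direct link with p = 0.5: 4 + 9 + 2 * (2 * 3 * 0.5) = 19
        d = -math.log(0.5) / calibrate_kernel(1.0).decay_rate
        linked = make_table([("a", 0, 0, 2.0), ("b", d, 0, 3.0)])
        net = prune_by_distance(build_complete_network(linked), d)
        net = assign_link_probabilities(net, calibrate_kernel(1.0))
        assert pc_numerator(max_product_paths(net), linked.areas) == pytest.approx(19.0)

    def test_self_pair_switch(self, rng):
        net = pruned_random_net(rng, 10)
        pairs = max_product_paths(net)
        a = net.nodes.areas
        with_self = pc_numerator(pairs, a, include_self=True)
        without = pc_numerator(pairs, a, include_self=False)
        assert with_self - without == pytest.approx(np.sum(a * a), rel=1e-12)
        assert with_self >= np.sum(a * a)

    def test_invalid_areas_rejected(self, rng):
        net = pruned_random_net(rng, 4)
        pairs = max_product_paths(net)
        with pytest.raises(ValidationError):
            pc_numerator(pairs, [1.0, 2.0])  # wrong length
        with pytest.raises(ValidationError):
            pc_numerator(pairs, [1.0, -2.0, 1.0, 1.0])


class TestNodeImportance:
    def test_symmetric_pair_has_equal_dpc(self):
        table = make_table([("a", 0, 0, 5_000.0), ("b", 2_000, 0, 5_000.0)])
        net = prune_by_distance(build_complete_network(table), 3_000.0)
        res = node_importance(net, calibrate_kernel(3_000.0))
        assert res.dpc[0] == pytest.approx(res.dpc[1])

    def test_isolated_node_loses_only_self_term(self, rng):
        table = make_table(
            [("a", 0, 0, 2_000.0), ("b", 1_000, 0, 3_000.0),
             ("iso", 500_000, 0, 7_000.0)]
        )
        net = prune_by_distance(build_complete_network(table), 5_000.0)
        res = node_importance(net, calibrate_kernel(5_000.0))
        k = res.ids.index("iso")
        assert res.dpc[k] == pytest.approx(100.0 * 7_000.0**2 / res.pc, rel=1e-12)

    def test_single_node_scores_100(self):
        table = make_table([("only", 0, 0, 1_234.0)])
        res = node_importance(build_complete_network(table), calibrate_kernel(1.0))
        assert res.dpc[0] == pytest.approx(100.0)
        assert res.rank[0] == 1

    def test_matches_naive_leave_one_out_oracle(self, rng):
        net = pruned_random_net(rng, 10)
        kernel = calibrate_kernel(6_000.0)
        res = node_importance(net, kernel)
        areas = net.nodes.areas
        full = brute_force_pairs(net)
        pc = areas @ full @ areas
        for k in range(10):
            keep = [i for i in range(10) if i != k]
            sub_table = net.nodes.subset([i != k for i in range(10)])
            sub = prune_by_distance(build_complete_network(sub_table), 6_000.0)
            sub = assign_link_probabilities(sub, kernel)
            sub_pairs = brute_force_pairs(sub)
            pc_minus = areas[keep] @ sub_pairs @ areas[keep]
            assert res.dpc[k] == pytest.approx(100 * (pc - pc_minus) / pc, abs=1e-9)

    def test_dpc_bounds_and_rank_permutation(self, rng):
        net = pruned_random_net(rng, 15)
        res = node_importance(net, calibrate_kernel(6_000.0))
        assert np.all(res.dpc >= -1e-12) and np.all(res.dpc <= 100 + 1e-12)
        assert sorted(res.rank) == list(range(1, 16))

    def test_area_alone_does_not_determine_rank(self):
        """A huge but remote waterhole can rank below small, central ones."""
        table = make_table(
            [("big_far", 100_000, 0, 15_000.0),
             ("s1", 0, 0, 10_000.0), ("s2", 200, 0, 10_000.0),
             ("s3", 100, 180, 10_000.0), ("s4", 100, -180, 10_000.0)]
        )
        net = prune_by_distance(build_complete_network(table), 2_000.0)
        res = node_importance(net, calibrate_kernel(2_000.0))
        big_rank = res.rank[res.ids.index("big_far")]
        assert big_rank > 1  # despite having by far the largest area


class TestAggregate:
    def test_single_distance_identity(self, rng):
        net = pruned_random_net(rng, 8)
        res = node_importance(net, calibrate_kernel(6_000.0))
        df = aggregate_importance([res])
        np.testing.assert_allclose(df["dPC_aggregate"], res.dpc)
        np.testing.assert_array_equal(df["rank"], res.rank)

    def test_three_distance_stack_sums_elementwise(self, rng):
        table = random_table(rng, 12)
        complete = build_complete_network(table)
        results = []
        for d in (4_000.0, 8_000.0, 12_000.0):
            results.append(
                node_importance(prune_by_distance(complete, d), calibrate_kernel(d))
            )
        df = aggregate_importance(results)
        expected = sum(r.dpc for r in results)
        np.testing.assert_allclose(df["dPC_aggregate"], expected, rtol=1e-12)
        order = np.argsort(-df["dPC_aggregate"].to_numpy(), kind="stable")
        assert df["rank"].iloc[order[0]] == 1

    def test_identical_results_scale_by_count(self, rng):
        net = pruned_random_net(rng, 6)
        res = node_importance(net, calibrate_kernel(6_000.0))
        df = aggregate_importance([res] * 5)
        np.testing.assert_allclose(df["dPC_aggregate"], 5 * res.dpc, rtol=1e-12)
        np.testing.assert_array_equal(df["rank"], res.rank)

    def test_mismatched_node_sets_rejected(self, rng):
        n1 = pruned_random_net(rng, 6)
        n2 = pruned_random_net(rng, 7)
        r1 = node_importance(n1, calibrate_kernel(6_000.0))
        r2 = node_importance(n2, calibrate_kernel(6_000.0))
        with pytest.raises(ValidationError):
            aggregate_importance([r1, r2])
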
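"""Merge-gain computation, super-edge classification and the main loop."""

import itertools
import math

import numpy as np
import pytest

from hamnet.graph import Graph, Partition
from hamnet.merge_engine import original_phase
from hamnet.quality import modularity
from hamnet.similarity import weight_edges
from hamnet.supernode_phase import classify_super_edges, delta_q, run_ham
from hamnet.synth_networks import clique_pair, clique_ring

from conftest import random_connected_graph


def brute_force_max_modularity(g: Graph) -> float:
    """Exhaustive search over all set partitions (feasible for <= 8 nodes)."""
    nodes = sorted(g.nodes)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1:]
            yield smaller + [[first]]

    best = -math.inf
    for blocks in partitions(nodes):
        q = modularity(g, Partition.from_communities(blocks))
        best = max(best, q)
    return best


class TestDeltaQ:
    def test_adjacent_clique_pair_gain(self):
        # two K5 ring cliques joined by one bridge in the 330-edge ring
        got = delta_q(10, 10, 22, 22, 1, 330)
        assert got == pytest.approx(1 / 330 - 968 / (4 * 330 ** 2), abs=1e-15)
        assert got == pytest.approx(8.0808e-4, abs=1e-8)

    def test_unconnected_communities_never_gain(self):
        assert delta_q(3, 4, 10, 12, 0, 50) < 0

    def test_degenerate_zero_degree(self):
        assert delta_q(0, 5, 0, 20, 2, 40) == pytest.approx(2 / 40)

    def test_zero_total_edges_rejected(self):
        with pytest.raises(ValueError):
            delta_q(1, 1, 2, 2, 1, 0)

    def test_matches_modularity_difference_exactly(self):
        """dQ must equal Q(merged) - Q(split) for every community pair of a
        random partition, to 1e-12."""
        rng = np.random.default_rng(101)
        for _ in range(60):
            g = random_connected_graph(rng, n=int(rng.integers(4, 30)))
            if g.n_edges == 0:
                continue
            nodes = sorted(g.nodes)
            k = int(rng.integers(2, min(6, len(nodes)) + 1))
            labels = rng.integers(0, k, len(nodes))
            part = Partition({v: str(c) for v, c in zip(nodes, labels)})
            comms = part.communities
            stats = {}
            for c, members in comms.items():
                l = sum(1 for i, j in g.edges() if i in members and j in members)
                d = sum(g.degree(v) for v in members)
                stats[c] = (l, d)
            base = modularity(g, part)
            for ca, cb in itertools.combinations(comms, 2):
                e_between = sum(
                    1 for i, j in g.edges()
                    if {part.assignment[i], part.assignment[j]} == {ca, cb})
                merged = Partition({
                    v: (ca if c == cb else c) for v, c in part.assignment.items()})
                gain = modularity(g, merged) - base
                la, da = stats[ca]
                lb, db = stats[cb]
                assert delta_q(la, lb, da, db, e_between, g.n_edges) == pytest.approx(
                    gain, abs=1e-12)


class TestClassifySuperEdges:
    def test_ring_level_one_has_no_merge_candidates(self):
        g, _ = clique_ring(5, 30)
        net, _ = original_phase(g, weight_edges(g, "min"))
        merge_class, bypass = classify_super_edges(net)
        # the 30 ring super-edges all carry w_hat = 0: positive dQ is not enough
        assert merge_class == []
        assert len(bypass) == 30
        assert all(se.delta_q is not None for se in bypass)

    def test_positive_weight_and_gain_lands_in_merge_class(self):
        # two triangles sharing two connecting edges with common neighbors
        g = Graph([("a", "b"), ("b", "c"), ("c", "a"),
                   ("d", "e"), ("e", "f"), ("f", "d"),
                   ("a", "d"), ("a", "e"), ("d", "b")])
        net, _ = original_phase(g, weight_edges(g, "min"))
        merge_class, bypass = classify_super_edges(net)
        for se in merge_class:
            assert se.w_hat > 0 and se.delta_q > 0
        for se in bypass:
            assert se.w_hat <= 0 or se.delta_q <= 0

    def test_merge_class_sorted_by_gain_then_weight(self):
        rng = np.random.default_rng(7)
        g = random_connected_graph(rng, n=25, p=0.2)
        net, _ = original_phase(g, weight_edges(g, "min"))
        merge_class, _ = classify_super_edges(net)
        keys = [(-se.delta_q, -se.w_hat, se.endpoints) for se in merge_class]
        assert keys == sorted(keys)


class TestRunHam:
    def test_clique_ring_resists_resolution_limit(self):
        g, truth = clique_ring(5, 30)
        res = run_ham(g, measure="min", w_threshold=0.0, epsilon=0.0)
        assert res.final_partition == truth
        assert round(res.final_q, 4) == 0.8758

    def test_clique_pair_small_cliques_survive(self):
        g, truth = clique_pair(20, 5)
        res = run_ham(g, measure="min")
        assert res.final_partition == truth
        assert round(res.final_q, 4) == 0.5416

    def test_two_triangles_joined_by_bridge_stay_separate(self):
        g = Graph([("a", "b"), ("b", "c"), ("c", "a"),
                   ("d", "e"), ("e", "f"), ("f", "d"), ("c", "d")])
        res = run_ham(g, measure="min")
        assert res.final_partition == Partition.from_communities(["abc", "def"])

    def test_single_edge_graph(self):
        res = run_ham(Graph([("a", "b")]))
        assert res.final_partition.n_communities == 1
        assert res.final_q == 0.0

    def test_accepted_levels_strictly_improve(self):
        rng = np.random.default_rng(71)
        for _ in range(15):
            g = random_connected_graph(rng, n=30, p=0.15)
            res = run_ham(g, measure="min")
            qs = [q for _, q in res.levels]
            assert all(b > a for a, b in zip(qs, qs[1:]))

    def test_each_level_coarsens_the_previous(self):
        rng = np.random.default_rng(73)
        for _ in range(15):
            g = random_connected_graph(rng, n=30, p=0.15)
            res = run_ham(g, measure="min")
            for (prev, _), (nxt, _) in zip(res.levels, res.levels[1:]):
                prev_comms = prev.communities.values()
                nxt_comms = list(nxt.communities.values())
                for block in prev_comms:
                    assert any(block <= big for big in nxt_comms)

    def test_final_q_bounded_by_exhaustive_maximum(self):
        rng = np.random.default_rng(79)
        for _ in range(12):
            g = random_connected_graph(rng, n=int(rng.integers(3, 9)), p=0.5)
            if g.n_edges == 0:
                continue
            res = run_ham(g, measure="min")
            assert res.final_q <= brute_force_max_modularity(g) + 1e-12

    def test_disconnected_input_modes(self):
        g = Graph([("a", "b"), ("b", "c"), ("c", "a"), ("x", "y")])
        res_gcc = run_ham(g, on_disconnected="gcc")
        assert res_gcc.final_partition.nodes == {"a", "b", "c"}
        res_all = run_ham(g, on_disconnected="components")
        assert res_all.final_partition.nodes == g.nodes
        with pytest.raises(ValueError):
            run_ham(g, on_disconnected="error")

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            run_ham(Graph())

    def test_clique_line_star_chain_overmerges_by_default(self):
        """Absorption-default structure maintenance swallows star communities
        hanging off a clique; bridge retention recovers the planted split."""
        from hamnet.quality import nmi
        from hamnet.synth_networks import clique_line

        g, truth = clique_line(5, 1, 4, 3)
        default = run_ham(g, measure="min")
        assert default.final_partition.n_communities < truth.n_communities
        assert nmi(default.final_partition, truth) < 1.0
        retained = run_ham(g, measure="min", bridge_retain=True)
        assert retained.final_partition == truth

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(83)
        g = random_connected_graph(rng, n=40, p=0.12)
        first = run_ham(g, measure="cosine")
        again = run_ham(g, measure="cosine")
        assert first.final_partition == again.final_partition
        assert first.final_q == again.final_q
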
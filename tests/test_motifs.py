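import math

import numpy as np
import pytest

from conftest import random_connected_net, tt_graph
from oracles import rational_codelength
from knms.motifs import (
    brute_force_partition,
    codelength,
    detect_motifs,
    module_significance,
    optimize_partition,
    visit_rates,
)
from knms.types import CTNetwork, Partition


TRIANGLES = [("a", "b"), ("b", "c"), ("a", "c"),
             ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")]


class TestVisitRates:
    def test_regular_graph_uniform(self):
        net = tt_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert all(abs(p - 0.25) < 1e-15 for p in visit_rates(net).values())

    def test_path_degree_proportional(self):
        net = tt_graph([("a", "b"), ("b", "c")])
        rates = visit_rates(net)
        assert rates == {"a": 0.25, "b": 0.5, "c": 0.25}

    def test_single_edge(self):
        assert visit_rates(tt_graph([("a", "b")])) == {"a": 0.5, "b": 0.5}

    def test_rates_sum_to_one_weighted(self):
        net = tt_graph([("a", "b"), ("b", "c"), ("c", "a")], weights=[0.5, 2.0, 3.25])
        assert math.isclose(sum(visit_rates(net).values()), 1.0, abs_tol=1e-12)

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            visit_rates(CTNetwork())


class TestCodelength:
    def test_four_cycle_one_module_is_entropy(self):
        net = tt_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        terms = codelength(net, Partition.one_module("abcd"))
        assert terms.codelength == 2.0
        assert terms.q_enter_total == 0.0

    def test_single_edge_singletons(self):
        net = tt_graph([("a", "b")])
        assert codelength(net, Partition.singletons("ab")).codelength == 3.0

    def test_two_triangles_matches_rational_oracle(self):
        net = tt_graph(TRIANGLES)
        part = Partition({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "f": 2})
        expected = rational_codelength([(u, v, 1) for u, v in TRIANGLES],
                                       [{"a", "b", "c"}, {"d", "e", "f"}])
        terms = codelength(net, part)
        assert abs(terms.codelength - expected) < 1e-9
        # exit rates: one bridge edge of the 7, so q_i = 1/14 per module
        assert all(abs(q - 1 / 14) < 1e-15 for q in terms.q_exit_i.values())

    def test_undirected_entry_equals_exit(self):
        net = tt_graph(TRIANGLES)
        part = Partition({"a": 1, "b": 1, "c": 2, "d": 2, "e": 3, "f": 3})
        terms = codelength(net, part)
        assert terms.q_enter_i == terms.q_exit_i

    def test_partition_must_cover_graph(self):
        net = tt_graph([("a", "b")])
        with pytest.raises(ValueError, match="cover"):
            codelength(net, Partition({"a": 1}))

    def test_random_graphs_match_rational_oracle(self):
        """Implementation vs exact-rational evaluation on 60 random graphs."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            net = random_connected_net(rng)
            nodes = sorted(net.graph.nodes)
            labels = {n: int(rng.integers(1, 4)) for n in nodes}
            part = Partition(labels)
            edges = [(u, v, 1) for u, v, _ in net.edges()]
            modules = [set(m) for m in part.members.values()]
            expected = rational_codelength(edges, modules)
            assert abs(codelength(net, part).codelength - expected) < 1e-9


class TestOptimizer:
    def test_complete_graph_one_module(self):
        net = tt_graph([("a", "b"), ("a", "c"), ("a", "d"),
                        ("b", "c"), ("b", "d"), ("c", "d")])
        result = optimize_partition(net, trials=5, seed=0)
        assert result.partition.n_modules == 1

    def test_two_triangles_recovered_exactly(self):
        net = tt_graph(TRIANGLES)
        result = optimize_partition(net, trials=5, seed=0)
        assert set(result.partition.members.values()) == \
            {frozenset("abc"), frozenset("def")}

    def test_deterministic_under_seed(self):
        net = tt_graph(TRIANGLES)
        a = optimize_partition(net, trials=8, seed=123)
        b = optimize_partition(net, trials=8, seed=123)
        assert a.partition == b.partition
        assert a.terms.codelength == b.terms.codelength

    def test_never_worse_than_trivial_partitions(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            net = random_connected_net(rng)
            nodes = net.graph.nodes
            result = optimize_partition(net, trials=3, seed=int(rng.integers(1 << 31)))
            bound = min(codelength(net, Partition.one_module(nodes)).codelength,
                        codelength(net, Partition.singletons(nodes)).codelength)
            assert result.terms.codelength <= bound + 1e-12

    def test_rejects_disconnected_and_bad_trials(self):
        net = tt_graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="connected"):
            optimize_partition(net, trials=1, seed=0)
        with pytest.raises(ValueError, match="trials"):
            optimize_partition(tt_graph([("a", "b")]), trials=0, seed=0)


class TestBruteForce:
    def test_single_edge_prefers_one_module(self):
        part, L = brute_force_partition(tt_graph([("a", "b")]))
        assert part.n_modules == 1 and L == 1.0

    def test_triangle_one_module(self):
        part, _ = brute_force_partition(tt_graph([("a", "b"), ("b", "c"), ("a", "c")]))
        assert part.n_modules == 1

    def test_guards(self):
        big = tt_graph([(f"n{i}", f"n{i+1}") for i in range(11)])
        with pytest.raises(ValueError, match="n <= 10"):
            brute_force_partition(big)
        with pytest.raises(ValueError, match="connected"):
            brute_force_partition(tt_graph([("a", "b"), ("c", "d")]))

    def test_optimizer_matches_oracle_on_small_graphs(self):
        rng = np.random.default_rng(555)
        for _ in range(25):
            net = random_connected_net(rng, n_max=7)
            _, best_L = brute_force_partition(net)
            result = optimize_partition(net, trials=10, seed=int(rng.integers(1 << 31)))
            assert abs(result.terms.codelength - best_L) < 1e-9


class TestSignificance:
    def test_zero_internal_edges_gives_p_one(self):
        # modules {a,c} and {b,d} of a 4-cycle have no internal edges
        net = tt_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        part = Partition({"a": 1, "c": 1, "b": 2, "d": 2})
        p, _, knms = module_significance(net, part, n_null=49, seed=0)
        assert p == {1: 1.0, 2: 1.0}
        assert knms == set()

    def test_planted_clique_maximally_significant(self):
        rng = np.random.default_rng(3)
        clique = [f"k{i}" for i in range(6)]
        edges = [(a, b) for i, a in enumerate(clique) for b in clique[i + 1:]]
        outside = [f"o{i}" for i in range(30)]
        # sparse random background ring plus a few chords, attached to the clique
        edges += [(outside[i], outside[(i + 1) % 30]) for i in range(30)]
        edges += [("k0", "o0"), ("k3", "o15")]
        net = tt_graph(edges)
        part = Partition({**{n: 1 for n in clique}, **{n: 2 for n in outside}})
        p, _, _ = module_significance(net, part, n_null=199, seed=11)
        assert p[part.module_of("k0")] == 1 / 200

    def test_singleton_module_defined_and_nonsignificant(self):
        net = tt_graph(TRIANGLES)
        part = Partition({"a": 1, "b": 2, "c": 2, "d": 2, "e": 2, "f": 2})
        p, q, knms = module_significance(net, part, n_null=49, seed=0)
        assert p[part.module_of("a")] == 1.0
        assert part.module_of("a") not in knms

    def test_requires_enough_nulls(self):
        net = tt_graph([("a", "b")])
        with pytest.raises(ValueError, match="n_null"):
            module_significance(net, Partition.one_module("ab"), n_null=5, seed=0)


class TestDetectMotifs:
    def test_disconnected_input_renumbers_globally(self):
        net = tt_graph(TRIANGLES + [("x", "y"), ("y", "z"), ("x", "z")])
        result = detect_motifs(net, trials=4, seed=5, significance=False)
        assert result.partition.nodes() == set(net.graph.nodes)
        members = set(result.partition.members.values())
        assert frozenset("xyz") in members

    def test_isolated_nodes_dropped_with_warning(self, caplog):
        net = tt_graph(TRIANGLES)
        net.add_target("lonely")
        with caplog.at_level("WARNING"):
            result = detect_motifs(net, trials=3, seed=1, significance=False)
        assert "lonely" not in result.partition.nodes()
        assert "isolated" in caplog.text

    def test_full_run_reports_significance(self):
        net = tt_graph(TRIANGLES)
        result = detect_motifs(net, trials=4, n_null=49, seed=9)
        assert set(result.p_values) == set(result.partition.module_ids)
        assert set(result.q_values) == set(result.partition.module_ids)
        assert result.knms <= set(result.partition.module_ids)
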
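"""Modularity and greedy agglomerative community detection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from psychoweb import Partition, build_graph, greedy_modularity_partition, modularity
from psychoweb.graph import SymptomGraph

from conftest import block_correlation, make_graph


def modularity_oracle(sg, membership):
    """Independent brute-force double-loop weighted modularity."""
    nodes = [n for n, d in sg.graph.degree if d > 0]
    w = {
        (a, b): abs(d["weight"])
        for a, b, d in sg.graph.edges(data=True)
    }

    def wt(a, b):
        return w.get((a, b), w.get((b, a), 0.0))

    two_w = sum(wt(a, b) for a in nodes for b in nodes)
    s = {a: sum(wt(a, b) for b in nodes) for a in nodes}
    q = 0.0
    for a in nodes:
        for b in nodes:
            if membership[a] == membership[b]:
                q += wt(a, b) - s[a] * s[b] / two_w
    return q / two_w


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def exhaustive_max_modularity(sg):
    nodes = sorted(n for n, d in sg.graph.degree if d > 0)
    best, best_part = -np.inf, None
    for part in set_partitions(nodes):
        membership = {n: i for i, block in enumerate(part) for n in block}
        q = modularity_oracle(sg, membership)
        if q > best:
            best, best_part = q, part
    return best, best_part


def random_weighted_graph(n, seed, p=0.6):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                g.add_edge(f"n{i}", f"n{j}", weight=float(rng.uniform(0.2, 0.9)))
    if g.number_of_edges() == 0:
        g.add_edge("n0", "n1", weight=0.5)
    return SymptomGraph(g)


def planted_two_block_graph(n, seed):
    """Small weighted graph with two planted modules (the guard suite)."""
    rng = np.random.default_rng(seed)
    split = n // 2
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < split) == (j < split)
            if same:
                g.add_edge(f"n{i}", f"n{j}", weight=float(rng.uniform(0.5, 0.9)))
            elif rng.random() < 0.4:
                g.add_edge(f"n{i}", f"n{j}", weight=float(rng.uniform(0.05, 0.2)))
    return SymptomGraph(g)


class TestModularity:
    def test_single_module_is_zero(self):
        g = make_graph([("a", "b", 0.5), ("b", "c", 0.3), ("a", "c", 0.8)])
        p = Partition({"a": 1, "b": 1, "c": 1})
        assert modularity(g, p) == pytest.approx(0.0, abs=1e-14)

    def test_two_disjoint_cliques_half(self):
        edges = [("a", "b", 0.4), ("b", "c", 0.4), ("a", "c", 0.4),
                 ("x", "y", 0.4), ("y", "z", 0.4), ("x", "z", 0.4)]
        g = make_graph(edges)
        p = Partition({"a": 1, "b": 1, "c": 1, "x": 2, "y": 2, "z": 2})
        assert modularity(g, p) == pytest.approx(0.5, abs=1e-14)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        g = random_weighted_graph(7, seed)
        rng = np.random.default_rng(seed + 100)
        active = [n for n, d in g.graph.degree if d > 0]
        membership = {n: int(rng.integers(0, 3)) for n in active}
        p = Partition(membership)
        assert modularity(g, p) == pytest.approx(
            modularity_oracle(g, membership), abs=1e-12
        )

    def test_negative_weights_use_absolute_value(self):
        pos = make_graph([("a", "b", 0.4), ("c", "d", 0.4), ("b", "c", 0.1)])
        neg = make_graph([("a", "b", -0.4), ("c", "d", 0.4), ("b", "c", -0.1)])
        p = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        assert modularity(pos, p) == pytest.approx(modularity(neg, p), abs=1e-14)

    def test_partition_must_cover_active_nodes(self):
        g = make_graph([("a", "b", 0.5)])
        with pytest.raises(ValueError):
            modularity(g, Partition({"a": 1}))

    def test_agrees_with_networkx(self):
        g = random_weighted_graph(8, 5)
        res = greedy_modularity_partition(g)
        h = g.graph.copy()
        communities = [set(v) for v in res.partition.modules.values()]
        nx_q = nx.community.modularity(h, communities, weight="weight")
        assert res.modularity_q == pytest.approx(nx_q, abs=1e-10)


class TestGreedy:
    def test_two_cliques_with_weak_bridge_recovered(self):
        edges = [(a, b, 0.6) for a, b in itertools.combinations("abcd", 2)]
        edges += [(a, b, 0.6) for a, b in itertools.combinations("wxyz", 2)]
        edges += [("d", "w", 0.05)]
        g = make_graph(edges)
        res = greedy_modularity_partition(g)
        mods = {frozenset(v) for v in res.partition.modules.values()}
        assert mods == {frozenset("abcd"), frozenset("wxyz")}
        best_q, _ = exhaustive_max_modularity(g)
        assert res.modularity_q == pytest.approx(best_q, abs=1e-12)

    def test_edgeless_components_stay_separate(self):
        g = make_graph([("a", "b", 0.5), ("x", "y", 0.5)])
        res = greedy_modularity_partition(g)
        mods = {frozenset(v) for v in res.partition.modules.values()}
        assert mods == {frozenset("ab"), frozenset("xy")}

    def test_planted_six_blocks_recovered_after_pruning(self):
        bc = block_correlation((4,) * 6, within=0.5, between=0.1)
        g = build_graph(bc)
        weak = [(a, b) for a, b, d in g.graph.edges(data=True) if abs(d["weight"]) < 0.3]
        g.graph.remove_edges_from(weak)
        res = greedy_modularity_partition(g)
        mods = {frozenset(v) for v in res.partition.modules.values()}
        items = bc.items
        expected = {frozenset(items[i : i + 4]) for i in range(0, 24, 4)}
        assert mods == expected

    def test_q_trace_strictly_increasing_and_consistent(self):
        g = random_weighted_graph(8, 3)
        res = greedy_modularity_partition(g)
        assert all(dq > 0 for _, _, dq in res.merge_trace)
        assert res.modularity_q == pytest.approx(
            modularity(g, res.partition), abs=1e-10
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_close_to_exhaustive_optimum(self, seed):
        """On every modular suite graph, greedy Q >= 0.97 x exhaustive max Q."""
        n = 5 + seed % 4
        g = planted_two_block_graph(n, seed)
        res = greedy_modularity_partition(g)
        best_q, _ = exhaustive_max_modularity(g)
        assert res.modularity_q >= 0.97 * best_q - 1e-12

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_networkx_greedy_on_random_graphs(self, seed):
        """Independent cross-check: identical Q to networkx's CNM variant,
        including unstructured graphs where greedy is suboptimal."""
        g = random_weighted_graph(5 + seed % 4, seed)
        res = greedy_modularity_partition(g)
        nx_comm = nx.community.greedy_modularity_communities(g.graph, weight="weight")
        nx_q = nx.community.modularity(g.graph, nx_comm, weight="weight")
        assert res.modularity_q == pytest.approx(nx_q, abs=1e-10)

    def test_invariant_to_node_relabeling(self):
        g = random_weighted_graph(7, 9)
        mapping = {n: f"z{ord(n[1])}" for n in g.graph.nodes}
        h = SymptomGraph(nx.relabel_nodes(g.graph, mapping))
        res_g = greedy_modularity_partition(g)
        res_h = greedy_modularity_partition(h)
        mods_g = {frozenset(mapping[n] for n in v) for v in res_g.partition.modules.values()}
        mods_h = {frozenset(v) for v in res_h.partition.modules.values()}
        assert mods_g == mods_h
        assert res_g.modularity_q == pytest.approx(res_h.modularity_q, abs=1e-12)

    def test_isolates_reported_not_clustered(self):
        g = make_graph([("a", "b", 0.5)])
        g.graph.add_node("lonely")
        res = greedy_modularity_partition(g)
        assert res.partition.isolates == {"lonely"}
        assert res.partition.items == {"a", "b"}
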
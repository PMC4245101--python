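"""Weighted node metrics, bridge/core classification, small-worldness, ANOVA."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from psychoweb import (
    Partition,
    bridge_core_summary,
    compare_groups,
    node_metrics,
    small_worldness,
)
from psychoweb.graph import SymptomGraph

from conftest import make_graph


def centrality_oracle(sg):
    """All-pairs path-enumeration oracle for weighted betweenness/closeness.

    Enumerates every simple path, scores it by summed 1/|r| edge lengths,
    and counts fractional shortest-path shares by hand.
    """
    g = sg.graph
    nodes = sorted(g.nodes)
    betw = {n: 0.0 for n in nodes}
    dist = {}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        lengths = [
            sum(1.0 / abs(g.edges[a, b]["weight"]) for a, b in zip(p, p[1:]))
            for p in paths
        ]
        d = min(lengths)
        dist[(s, t)] = dist[(t, s)] = d
        shortest = [p for p, l in zip(paths, lengths) if l <= d * (1 + 1e-12)]
        for p in shortest:
            for v in p[1:-1]:
                betw[v] += 1.0 / len(shortest)
    close = {
        n: (len(nodes) - 1) / sum(dist[(n, o)] for o in nodes if o != n) for n in nodes
    }
    return betw, close


def connected_random_graph(n, seed):
    rng = np.random.default_rng(seed)
    while True:
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
        if nx.is_connected(g) and g.number_of_edges() > n:
            break
    h = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    for _, _, d in h.edges(data=True):
        d["weight"] = float(rng.uniform(0.2, 0.9)) * (1 if rng.random() < 0.8 else -1)
    return SymptomGraph(h)


def two_cluster_partition(sg, seed=0):
    rng = np.random.default_rng(seed)
    nodes = sorted(sg.graph.nodes)
    return Partition({n: int(rng.integers(1, 3)) for n in nodes})


class TestNodeMetrics:
    def test_path_graph_hand_values(self):
        g = make_graph([("a", "b", 1.0), ("b", "c", 1.0)])
        p = Partition({"a": 1, "b": 1, "c": 1})
        m = node_metrics(g, p)
        assert m.loc["b", "w_betweenness"] == 1.0
        assert m.loc["a", "w_betweenness"] == 0.0
        assert m.loc["b", "w_closeness"] == pytest.approx(1.0)
        assert m.loc["a", "w_closeness"] == pytest.approx(2 / 3)  # dists 1 and 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_centralities_match_path_enumeration_oracle(self, seed):
        g = connected_random_graph(7, seed)
        p = two_cluster_partition(g, seed)
        m = node_metrics(g, p)
        betw, close = centrality_oracle(g)
        for n in g.graph.nodes:
            assert m.loc[n, "w_betweenness"] == pytest.approx(betw[n], abs=1e-9)
            assert m.loc[n, "w_closeness"] == pytest.approx(close[n], rel=1e-9)

    def test_weighted_degree_handshake(self):
        g = connected_random_graph(8, 7)
        p = two_cluster_partition(g, 7)
        m = node_metrics(g, p)
        total = sum(abs(d["weight"]) for _, _, d in g.graph.edges(data=True))
        assert m["w_degree"].sum() == pytest.approx(2 * total)
        assert (m["within_cluster_w_degree"] <= m["w_degree"] + 1e-12).all()

    def test_bridge_classification_and_external_counts(self):
        # b has the only cross-cluster edge; everything else internal
        g = make_graph(
            [("a", "b", 0.5), ("a", "c", 0.5), ("b", "c", 0.5),
             ("b", "x", 0.2), ("x", "y", 0.5)]
        )
        p = Partition({"a": 1, "b": 1, "c": 1, "x": 2, "y": 2})
        m = node_metrics(g, p)
        assert m.loc["b", "status"] == "Bridge"
        assert m.loc["b", "n_external_clusters"] == 1
        assert m.loc["a", "status"] == "Core"
        assert (m["n_external_clusters"] <= p.n_modules - 1).all()

    def test_removing_cross_edges_turns_bridge_into_core(self):
        g = make_graph(
            [("a", "b", 0.5), ("a", "c", 0.5), ("b", "c", 0.5),
             ("b", "x", 0.2), ("c", "x", 0.3), ("x", "y", 0.5)]
        )
        p = Partition({"a": 1, "b": 1, "c": 1, "x": 2, "y": 2})
        assert node_metrics(g, p).loc["b", "status"] == "Bridge"
        g.graph.remove_edge("b", "x")  # graph stays connected via c-x
        assert node_metrics(g, p).loc["b", "status"] == "Core"

    def test_log_transforms_are_log1p(self):
        g = make_graph([("a", "b", 1.0), ("b", "c", 1.0)])
        m = node_metrics(g, Partition({"a": 1, "b": 1, "c": 1}))
        assert m.loc["a", "ln_w_BS"] == 0.0  # ln(1+0): zero betweenness stays finite
        assert m.loc["b", "ln_w_D"] == pytest.approx(np.log1p(2.0))

    def test_disconnected_web_rejected(self):
        g = make_graph([("a", "b", 0.5), ("x", "y", 0.5)])
        p = Partition({"a": 1, "b": 1, "x": 2, "y": 2})
        with pytest.raises(ValueError, match="connected"):
            node_metrics(g, p)


class TestBridgeCoreSummary:
    def test_all_internal_partition(self):
        g = make_graph([("a", "b", 0.5), ("b", "c", 0.5)])
        m = node_metrics(g, Partition({"a": 1, "b": 1, "c": 1}))
        s = bridge_core_summary(m)
        assert s["n_bridge"] == 0 and s["pct_core"] == 100.0

    def test_counts_match_edge_scan_oracle(self):
        g = connected_random_graph(8, 11)
        p = two_cluster_partition(g, 11)
        m = node_metrics(g, p)
        bridges = set()
        for a, b in g.graph.edges:
            if p.membership[a] != p.membership[b]:
                bridges.update((a, b))
        s = bridge_core_summary(m)
        assert s["n_bridge"] == len(bridges)
        assert s["n_core"] == g.graph.number_of_nodes() - len(bridges)


class TestSmallWorldness:
    def test_random_graph_self_comparison_near_one(self):
        base = nx.gnm_random_graph(40, 200, seed=1)
        assert nx.is_connected(base)
        for _, _, d in base.edges(data=True):
            d["weight"] = 0.5
        sw = small_worldness(SymptomGraph(base), n_random=100, seed=2)
        assert sw.s == pytest.approx(1.0, abs=0.25)
        assert sw.s == pytest.approx(
            (sw.c_obs / sw.c_rand) / (sw.l_obs / sw.l_rand), abs=1e-12
        )

    def test_ring_lattice_is_small_world_positive(self):
        lattice = nx.watts_strogatz_graph(30, 4, p=0.0, seed=0)
        for _, _, d in lattice.edges(data=True):
            d["weight"] = 0.5
        sw = small_worldness(SymptomGraph(lattice), n_random=50, seed=3)
        assert sw.s > 1.0

    def test_disconnected_rejected(self):
        g = make_graph([("a", "b", 0.5), ("x", "y", 0.5)])
        with pytest.raises(ValueError):
            small_worldness(g, n_random=5, seed=0)


class TestCompareGroups:
    @staticmethod
    def metrics_frame(values, status, cluster=None):
        n = len(values)
        return pd.DataFrame(
            {
                "cluster": cluster if cluster is not None else [1] * n,
                "status": status,
                "n_external_clusters": [1 if s == "Bridge" else 0 for s in status],
                "ln_w_D": values,
                "ln_w_BS": values,
                "ln_w_CS": values,
                "ln_within_w_D": values,
            },
            index=[f"it{i:02d}" for i in range(n)],
        )

    def test_identical_groups_give_zero_f(self):
        df = self.metrics_frame([1.0] * 8, ["Bridge"] * 4 + ["Core"] * 4)
        res = compare_groups(df, dependent=("ln_w_D",))
        bridge = next(r for r in res if r.factor == "BRIDGE")
        assert bridge.f_stat == pytest.approx(0.0, abs=1e-20)

    def test_one_factor_f_equals_t_squared(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 10), rng.normal(0.8, 1, 12)
        values = np.concatenate([a, b])
        df = self.metrics_frame(values, ["Bridge"] * 10 + ["Core"] * 12)
        res = compare_groups(df, dependent=("ln_w_D",))
        bridge = next(r for r in res if r.factor == "BRIDGE")
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert bridge.f_stat == pytest.approx(t**2, rel=1e-10)
        assert bridge.df == (1.0, na + nb - 2)

    def test_two_factor_model_reports_all_terms(self):
        rng = np.random.default_rng(22)
        status = (["Bridge", "Core"] * 8)
        cluster = [1] * 8 + [2] * 8
        values = rng.normal(size=16) + [0.5 if s == "Bridge" else 0 for s in status]
        df = self.metrics_frame(values, status, cluster)
        res = compare_groups(df, dependent=("ln_w_D",))
        assert {r.factor for r in res} == {"CLUSTER", "BRIDGE", "CLUSTER:BRIDGE"}
        means = next(r for r in res if r.factor == "BRIDGE").group_means
        assert set(means["BRIDGE"]) == {0, 1}
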
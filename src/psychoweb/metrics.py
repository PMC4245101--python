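"""Weighted node metrics, bridge/core classification, small-worldness, GLM.

On the optimized web (a single connected component), every node gets:

* weighted degree w_D: sum of |r| over incident edges, and its
  within-cluster restriction;
* weighted betweenness w_BS and closeness w_CS: shortest paths computed by
  Dijkstra with edge length 1/|r| (a stronger correlation is a shorter
  distance); closeness is the inverse mean distance to all other nodes;
* local clustering coefficient (unweighted transitivity on the pruned
  graph);
* bridge/core status: a node with one or more direct edges into a foreign
  cluster is a bridge symptom, otherwise a core symptom, together with the
  count of distinct foreign clusters reached.

Log transforms use ln(1 + x) so zero-valued centralities stay finite.
Small-worldness compares mean clustering and mean hop path length against
uniformly random graphs with the same node and edge counts:
S = (C/C_rand) / (L/L_rand); S > 1 indicates small-world topology. Group
comparisons fit per-metric two-factor fixed-effects linear models with
CLUSTER, BRIDGE and their interaction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph import SymptomGraph
from .partition import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "NodeMetrics",
    "SmallWorldResult",
    "GroupComparisonResult",
    "node_metrics",
    "bridge_core_summary",
    "small_worldness",
    "compare_groups",
]


@dataclass(frozen=True)
class SmallWorldResult:
    """Observed vs random-reference clustering/path-length ratio."""

    c_obs: float
    l_obs: float
    c_rand: float
    l_rand: float
    s: float
    n_random: int
    seed: int


@dataclass(frozen=True)
class GroupComparisonResult:
    """One ANOVA term of a per-metric two-factor linear model."""

    metric: str
    factor: str  # CLUSTER, BRIDGE, or CLUSTER:BRIDGE
    f_stat: float
    df: tuple[float, float]
    p: float
    group_means: pd.DataFrame = field(repr=False)  # level, mean, se, n


#: Columns of the node-metrics table, in output order.
NodeMetrics = [
    "item",
    "cluster",
    "status",
    "n_external_clusters",
    "w_degree",
    "within_cluster_w_degree",
    "w_betweenness",
    "w_closeness",
    "ln_w_D",
    "ln_w_BS",
    "ln_w_CS",
    "ln_within_w_D",
    "clustering_coefficient",
]


def _abs_weighted(g: nx.Graph) -> nx.Graph:
    h = g.copy()
    for _, _, d in h.edges(data=True):
        d["absweight"] = abs(d["weight"])
        d["length"] = 1.0 / d["absweight"] if d["absweight"] > 0 else float("inf")
    return h


def node_metrics(web: SymptomGraph, ncs: Partition) -> pd.DataFrame:
    """Per-node weighted metrics and bridge/core status on the optimized web.

    The web must be a single connected component whose nodes are exactly
    the items of ``ncs``.
    """
    g = web.graph
    if set(g.nodes) != ncs.items:
        raise ValueError("partition must cover exactly the web's nodes")
    if g.number_of_nodes() > 1 and not nx.is_connected(g):
        raise ValueError("web must be connected; pass the main component")

    h = _abs_weighted(g)
    n = h.number_of_nodes()
    betw = nx.betweenness_centrality(h, weight="length", normalized=False)
    clust = nx.clustering(h)  # unweighted local transitivity

    dist = dict(nx.all_pairs_dijkstra_path_length(h, weight="length"))

    rows = []
    for node in sorted(h.nodes):
        cl = ncs.membership[node]
        wd = sum(d["absweight"] for _, _, d in h.edges(node, data=True))
        wd_in = sum(
            d["absweight"]
            for _, v, d in h.edges(node, data=True)
            if ncs.membership[v] == cl
        )
        ext = {ncs.membership[v] for v in h.neighbors(node) if ncs.membership[v] != cl}
        mean_dist = (
            sum(dist[node][o] for o in h.nodes if o != node) / (n - 1) if n > 1 else 0.0
        )
        wc = 1.0 / mean_dist if mean_dist > 0 else 0.0
        rows.append(
            {
                "item": node,
                "cluster": cl,
                "status": "Bridge" if ext else "Core",
                "n_external_clusters": len(ext),
                "w_degree": wd,
                "within_cluster_w_degree": wd_in,
                "w_betweenness": betw[node],
                "w_closeness": wc,
                "ln_w_D": float(np.log1p(wd)),
                "ln_w_BS": float(np.log1p(betw[node])),
                "ln_w_CS": float(np.log1p(wc)),
                "ln_within_w_D": float(np.log1p(wd_in)),
                "clustering_coefficient": clust[node],
            }
        )
    return pd.DataFrame(rows).set_index("item")


def bridge_core_summary(metrics: pd.DataFrame) -> dict:
    """Counts and shares of bridge vs core symptoms."""
    if metrics.empty:
        raise ValueError("empty metrics table")
    n = len(metrics)
    n_bridge = int((metrics["status"] == "Bridge").sum())
    n_core = n - n_bridge
    return {
        "n_nodes": n,
        "n_bridge": n_bridge,
        "n_core": n_core,
        "pct_bridge": 100.0 * n_bridge / n,
        "pct_core": 100.0 * n_core / n,
        "max_external_clusters": int(metrics["n_external_clusters"].max()),
    }


def small_worldness(
    web: SymptomGraph, n_random: int = 100, seed: int = 0
) -> SmallWorldResult:
    """Small-worldness S of the web against same-size uniform random graphs.

    S = (C_obs / C_rand) / (L_obs / L_rand) with C the mean clustering
    coefficient and L the mean shortest path length in hops; reference
    graphs share the node and edge counts and are resampled until
    connected (at most 100 tries each).
    """
    g = web.graph
    if not nx.is_connected(g):
        raise ValueError("web must be connected")
    n, m = g.number_of_nodes(), g.number_of_edges()
    c_obs = nx.average_clustering(g)
    l_obs = nx.average_shortest_path_length(g)

    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_random):
        for _try in range(100):
            ref = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
            if nx.is_connected(ref):
                break
        else:
            raise RuntimeError(
                "could not sample a connected reference graph; density too low"
            )
        cs.append(nx.average_clustering(ref))
        ls.append(nx.average_shortest_path_length(ref))
    c_rand, l_rand = float(np.mean(cs)), float(np.mean(ls))
    s = (c_obs / c_rand) / (l_obs / l_rand)
    return SmallWorldResult(
        c_obs=float(c_obs),
        l_obs=float(l_obs),
        c_rand=c_rand,
        l_rand=l_rand,
        s=float(s),
        n_random=n_random,
        seed=seed,
    )


def _term_means(df: pd.DataFrame, metric: str, by: list[str]) -> pd.DataFrame:
    grp = df.groupby(by, observed=True)[metric]
    out = grp.agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    return out.drop(columns="std")


def compare_groups(
    metrics: pd.DataFrame,
    dependent: tuple[str, ...] = ("ln_w_D", "ln_w_BS", "ln_w_CS", "ln_within_w_D"),
) -> list[GroupComparisonResult]:
    """Two-factor (CLUSTER, BRIDGE, interaction) ANOVA per metric.

    Levels observed only once trigger a warning and the interaction term
    is dropped; a factor with fewer than two levels is dropped entirely.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = metrics.reset_index().copy()
    df["CLUSTER"] = df["cluster"].astype(str)
    df["BRIDGE"] = (df["status"] == "Bridge").astype(int)

    factors = []
    if df["CLUSTER"].nunique() >= 2:
        factors.append("C(CLUSTER)")
    if df["BRIDGE"].nunique() >= 2:
        factors.append("C(BRIDGE)")
    if not factors:
        raise ValueError("need at least two groups on some factor")

    with_interaction = len(factors) == 2
    if with_interaction:
        cell_counts = df.groupby(["CLUSTER", "BRIDGE"], observed=True).size()
        if (cell_counts < 2).any():
            logger.warning(
                "design cells with a single observation; dropping CLUSTER:BRIDGE term"
            )
            with_interaction = False

    rhs = " + ".join(factors)
    if with_interaction:
        rhs += " + C(CLUSTER):C(BRIDGE)"

    results: list[GroupComparisonResult] = []
    for metric in dependent:
        model = smf.ols(f"{metric} ~ {rhs}", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(model, typ=2)
        resid_df = float(table.loc["Residual", "df"])
        for term in table.index:
            if term == "Residual":
                continue
            name = (
                term.replace("C(CLUSTER):C(BRIDGE)", "CLUSTER:BRIDGE")
                .replace("C(CLUSTER)", "CLUSTER")
                .replace("C(BRIDGE)", "BRIDGE")
            )
            by = ["CLUSTER", "BRIDGE"] if ":" in name else [name]
            # degenerate all-equal responses: no explained variation, F = 0
            if float(table.loc[term, "sum_sq"]) < 1e-12:
                f_stat, p_val = 0.0, 1.0
            else:
                f_stat = float(table.loc[term, "F"])
                p_val = float(table.loc[term, "PR(>F)"])
            results.append(
                GroupComparisonResult(
                    metric=metric,
                    factor=name,
                    f_stat=f_stat,
                    df=(float(table.loc[term, "df"]), resid_df),
                    p=p_val,
                    group_means=_term_means(df, metric, by),
                )
            )
    return results
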
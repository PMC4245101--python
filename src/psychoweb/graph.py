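"""Weighted undirected symptom graph and incremental edge pruning.

The unthresholded graph is complete: every item pair carries its signed
bootstrapped correlation as edge weight (no cutoff, so all correlations are
represented). Pruning removes edges one at a time in ascending order of
|r| (ties broken lexicographically on the node-label pair); nodes that lose
their last edge become isolates and are excluded from all further
calculations, and the count of connected components among the remaining
nodes tracks percolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .preprocess import BootCorrelation

__all__ = [
    "SymptomGraph",
    "PruneStep",
    "build_graph",
    "prune_schedule",
    "apply_steps",
    "main_component",
]


@dataclass
class SymptomGraph:
    """Undirected weighted graph over symptom items at a given |r| threshold."""

    graph: nx.Graph
    threshold: float = 0.0

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def active_nodes(self) -> list[str]:
        """Nodes that still have at least one edge (isolates excluded)."""
        return sorted(n for n, d in self.graph.degree if d > 0)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "SymptomGraph":
        return SymptomGraph(self.graph.copy(), self.threshold)

    def subgraph(self, nodes) -> "SymptomGraph":
        return SymptomGraph(self.graph.subgraph(nodes).copy(), self.threshold)

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, d["weight"], d.get("p", float("nan")))
            for a, b, d in self.graph.edges(data=True)
        ]
        rows = [(min(a, b), max(a, b), w, p) for a, b, w, p in rows]
        return pd.DataFrame(
            sorted(rows), columns=["item_a", "item_b", "r", "p"]
        )

    def to_edge_csv(self, path) -> None:
        self.edge_frame().to_csv(path, index=False)

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, _, d in g.edges(data=True):
            d["sign"] = 1 if d["weight"] >= 0 else -1
            d["abs_weight"] = abs(d["weight"])
        g.graph["threshold"] = self.threshold
        nx.write_graphml(g, path)


@dataclass(frozen=True)
class PruneStep:
    """One edge removal in the pruning schedule."""

    index: int
    edge: tuple[str, str]
    threshold_r: float  # |r| of the removed edge
    threshold_p: float  # bootstrap significance of the removed edge
    removed_edges: int  # cumulative count
    dropped_items: tuple[str, ...]  # nodes isolated at this step
    n_nodes: int  # non-isolate nodes remaining
    n_components: int  # connected components among remaining nodes


def build_graph(corr: BootCorrelation) -> SymptomGraph:
    """Complete signed-weight graph over all items, threshold 0."""
    items = corr.items
    g = nx.Graph()
    g.add_nodes_from(items)
    rv, pv = corr.r.to_numpy(), corr.p.to_numpy()
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            g.add_edge(items[i], items[j], weight=float(rv[i, j]), p=float(pv[i, j]))
    return SymptomGraph(g, threshold=0.0)


def _edge_order(g: nx.Graph) -> list[tuple[str, str]]:
    edges = [(min(a, b), max(a, b)) for a, b in g.edges]
    return sorted(edges, key=lambda e: (abs(g.edges[e]["weight"]), e))


def prune_schedule(sg: SymptomGraph) -> list[PruneStep]:
    """Remove edges one at a time in ascending |r| and record each step.

    Works on a copy; the input graph is untouched. At each step, nodes
    left without edges are recorded as dropped isolates; ``n_components``
    counts connected components among the surviving (non-isolate) nodes.
    """
    g = sg.graph.copy()
    order = _edge_order(g)
    steps: list[PruneStep] = []
    for i, (a, b) in enumerate(order):
        w = abs(g.edges[a, b]["weight"])
        p = g.edges[a, b].get("p", float("nan"))
        g.remove_edge(a, b)
        dropped = tuple(sorted(n for n in (a, b) if g.degree[n] == 0))
        g.remove_nodes_from(dropped)
        # also purge nodes isolated earlier (defensive; cannot occur here)
        alive = [n for n, d in g.degree if d > 0]
        n_comp = nx.number_connected_components(g.subgraph(alive)) if alive else 0
        steps.append(
            PruneStep(
                index=i,
                edge=(a, b),
                threshold_r=float(w),
                threshold_p=float(p),
                removed_edges=i + 1,
                dropped_items=dropped,
                n_nodes=len(alive),
                n_components=n_comp,
            )
        )
    return steps


def apply_steps(sg: SymptomGraph, steps: list[PruneStep], upto: int) -> SymptomGraph:
    """Graph state after applying schedule steps 0..upto inclusive.

    Isolated nodes are removed; the threshold is the |r| of the last
    removed edge.
    """
    g = sg.graph.copy()
    for step in steps[: upto + 1]:
        if g.has_edge(*step.edge):
            g.remove_edge(*step.edge)
    isolates = [n for n, d in g.degree if d == 0]
    g.remove_nodes_from(isolates)
    thr = steps[upto].threshold_r if upto >= 0 else 0.0
    return SymptomGraph(g, threshold=thr)


def main_component(sg: SymptomGraph) -> tuple[frozenset[str], int]:
    """Largest connected component (isolates excluded) and component count.

    Ties for largest are broken toward the component containing the
    smallest item label.
    """
    alive = [n for n, d in sg.graph.degree if d > 0]
    if not alive:
        raise ValueError("graph has no edges")
    comps = list(nx.connected_components(sg.graph.subgraph(alive)))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return frozenset(comps[0]), len(comps)
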
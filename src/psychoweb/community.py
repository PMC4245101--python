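"""Greedy agglomerative modularity maximization (Clauset-Newman-Moore).

Communities are found bottom-up: starting from singleton modules, the pair
of connected modules whose merger yields the largest modularity gain is
merged, until no merger increases Q. This is the plain CNM procedure
without consolidation heuristics, with deterministic tie-breaking (on equal
gain, the lexicographically smallest module-label pair merges; a module is
labeled by its smallest item).

Modularity is the weighted Newman measure

    Q = (1/2W) sum_ij [w_ij - s_i s_j / (2W)] delta(c_i, c_j)

computed on absolute correlation weights w = |r|, so strong negative
correlations bind as strongly as positive ones (switchable to signed
weights clipped at zero via ``use_abs=False``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import SymptomGraph
from .partition import Partition

__all__ = ["PartitionResult", "modularity", "greedy_modularity_partition"]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PartitionResult:
    """Community partition with its modularity and the greedy merge trace."""

    partition: Partition
    modularity_q: float
    merge_trace: tuple[tuple[str, str, float], ...]


def _weight_matrix(sg: SymptomGraph, use_abs: bool) -> tuple[list[str], np.ndarray]:
    nodes = sorted(sg.graph.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, d in sg.graph.edges(data=True):
        w = abs(d["weight"]) if use_abs else max(d["weight"], 0.0)
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    return nodes, a


def modularity(sg: SymptomGraph, p: Partition, use_abs: bool = True) -> float:
    """Weighted Newman modularity of a partition of the graph's active nodes."""
    active = set(sg.active_nodes)
    if p.items != active:
        raise ValueError("partition must cover exactly the graph's non-isolate nodes")
    nodes, a = _weight_matrix(sg.subgraph(active), use_abs)
    two_w = a.sum()
    if two_w <= 0:
        raise ValueError("graph has zero total weight")
    s = a.sum(axis=1)
    ids = {m: i for i, m in enumerate(dict.fromkeys(p.membership[n] for n in nodes))}
    comm = np.array([ids[p.membership[n]] for n in nodes])
    same = comm[:, None] == comm[None, :]
    q = (a[same].sum() - (np.outer(s, s)[same].sum()) / two_w) / two_w
    return float(q)


def greedy_modularity_partition(sg: SymptomGraph, use_abs: bool = True) -> PartitionResult:
    """CNM greedy modularity maximization with deterministic tie-breaking.

    Isolate nodes (degree 0) are excluded from the merge process and
    reported in the returned partition's ``isolates``.
    """
    isolates = sorted(set(sg.nodes) - set(sg.active_nodes))
    active = sg.active_nodes
    if not active:
        raise ValueError("graph has no edges")
    nodes, a = _weight_matrix(sg.subgraph(active), use_abs)
    n = len(nodes)
    two_w = a.sum()
    if two_w <= 0:
        raise ValueError("graph has zero total weight")

    em = a / two_w  # between-module weight fractions; diagonal = intra
    av = em.sum(axis=1)
    alive = np.ones(n, dtype=bool)
    labels = list(nodes)  # module label = smallest member item
    members: list[list[str]] = [[x] for x in nodes]

    q = -float((av**2).sum())
    trace: list[tuple[str, str, float]] = []

    while True:
        dq = 2.0 * (em - np.outer(av, av))
        mask = (em > 0) & alive[:, None] & alive[None, :]
        np.fill_diagonal(mask, False)
        if not mask.any():
            break
        best = dq[mask].max()
        if best <= 0:
            break
        # deterministic tie-break: smallest sorted (label, label) pair
        cand = np.argwhere(mask & (dq >= best - _TIE_TOL))
        pairs = {
            tuple(sorted((labels[i], labels[j]))): (i, j) for i, j in cand
        }
        la, lb = min(pairs)
        i, j = pairs[(la, lb)]
        t, s = (i, j) if labels[i] <= labels[j] else (j, i)
        gain = float(dq[t, s])

        em[t, :] += em[s, :]
        em[:, t] += em[:, s]
        av[t] += av[s]
        alive[s] = False
        em[s, :] = 0.0
        em[:, s] = 0.0
        av[s] = 0.0
        members[t].extend(members[s])
        members[s] = []
        labels[t] = min(labels[t], labels[s])
        q += gain
        trace.append((la, lb, gain))

    membership = {}
    for i in range(n):
        if alive[i]:
            for item in members[i]:
                membership[item] = labels[i]
    part = Partition(membership, frozenset(isolates)).relabeled()
    return PartitionResult(part, float(q), tuple(trace))
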
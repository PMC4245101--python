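"""Threshold-sweep optimization of the symptom web.

The core procedure: prune edges from the complete bootstrapped correlation
graph one at a time in ascending |r|; at every step detect the network
community structure (NCS) of the surviving graph; whenever an item has
dropped off, re-fit all candidate k-component principal-component
structures (PCS) on the correlation sub-matrix of the surviving items; and
score every NCS-vs-PCS comparison with the mismatch measure

    mismatch(cluster, component)
        = |cluster symmetric-difference component| / (|cluster| + |component|)

which is 0 for identical sets and 1 for disjoint ones. Clusters are paired
one-to-one with components by the assignment minimizing total mismatch.
The accepted optimum is the sweep record with the smallest mean per-pair
mismatch among records whose graph is unpercolated (a single connected
component) and retains at least a minimum fraction of the items; this
operationalizes the published rule of rejecting a deeper but percolated
minimum in favor of the best intact solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .community import greedy_modularity_partition
from .components import ComponentSolution, fit_components
from .graph import PruneStep, SymptomGraph, build_graph, prune_schedule
from .partition import Partition
from .preprocess import BootCorrelation, bootstrap_correlation_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "MatchResult",
    "SweepRecord",
    "SweepResult",
    "OptimalSolution",
    "mismatch_pair",
    "match_partitions",
    "sweep",
    "select_optimum",
    "dropoff_diagnostics",
]


def mismatch_pair(cluster_items: Iterable[str], component_items: Iterable[str]) -> float:
    """Relative mismatch between a cluster and a component.

    Symmetric difference divided by the sum of the two set sizes (the
    maximum possible mismatch), hence in [0, 1].
    """
    a, b = set(cluster_items), set(component_items)
    if not a or not b:
        raise ValueError("mismatch_pair requires two non-empty sets")
    return len(a ^ b) / (len(a) + len(b))


@dataclass(frozen=True)
class MatchResult:
    """Optimal cluster-to-component pairing with per-pair and overall scores."""

    pairing: dict[Hashable, Hashable]  # cluster id -> component id (real pairs only)
    per_pair_mismatch: dict[Hashable, float]  # cluster id -> score (1.0 if unmatched)
    mean_pair_mismatch: float
    disputed_items: frozenset[str]
    overall_mismatch: float  # |disputed| / |item universe|
    n_items: int


def match_partitions(ncs: Partition, pcs: Partition) -> MatchResult:
    """Pair network clusters to components minimizing total mismatch.

    Uses the optimal one-to-one assignment; when the cluster and component
    counts differ, the surplus is paired with an empty placeholder at
    mismatch 1.0. Disputed items are those whose cluster's paired component
    does not contain them or whose component's paired cluster does not
    contain them (counted once per item).
    """
    if ncs.items != pcs.items:
        raise ValueError("partitions must cover the identical item universe")
    universe = ncs.items
    cmods = ncs.modules
    pmods = pcs.modules
    cids = sorted(cmods, key=str)
    pids = sorted(pmods, key=str)
    n = max(len(cids), len(pids))
    cost = np.ones((n, n))
    for i, c in enumerate(cids):
        for j, p in enumerate(pids):
            cost[i, j] = mismatch_pair(cmods[c], pmods[p])
    rows, cols = linear_sum_assignment(cost)

    pairing: dict[Hashable, Hashable] = {}
    per_pair: dict[Hashable, float] = {}
    disputed: set[str] = set()
    scores: list[float] = []
    for i, j in zip(rows, cols):
        real_c, real_p = i < len(cids), j < len(pids)
        scores.append(float(cost[i, j]))
        if real_c and real_p:
            c, p = cids[i], pids[j]
            pairing[c] = p
            per_pair[c] = float(cost[i, j])
            disputed |= cmods[c] ^ pmods[p]
        elif real_c:
            per_pair[cids[i]] = 1.0
            disputed |= cmods[cids[i]]
        elif real_p:
            disputed |= pmods[pids[j]]

    return MatchResult(
        pairing=pairing,
        per_pair_mismatch=per_pair,
        mean_pair_mismatch=float(np.mean(scores)) if scores else 0.0,
        disputed_items=frozenset(disputed),
        overall_mismatch=len(disputed) / len(universe) if universe else 0.0,
        n_items=len(universe),
    )


@dataclass(frozen=True)
class SweepRecord:
    """NCS-vs-PCS comparison at one pruning step for one candidate k."""

    step: PruneStep
    k: int
    ncs: Partition
    pcs: Partition
    match: MatchResult
    n_nodes: int
    n_clusters: int
    percolated: bool

    @property
    def threshold_r(self) -> float:
        return self.step.threshold_r

    @property
    def threshold_p(self) -> float:
        return self.step.threshold_p


@dataclass
class SweepResult:
    """Full sweep trace plus the objects needed to reconstruct any state."""

    records: list[SweepRecord]
    corr: BootCorrelation
    base_graph: SymptomGraph
    schedule: list[PruneStep]
    ks: tuple[int, ...]

    def trace_frame(self) -> pd.DataFrame:
        """Long-format machine-readable sweep trace."""
        rows = [
            {
                "step": r.step.index,
                "threshold_r": r.threshold_r,
                "threshold_p": r.threshold_p,
                "k": r.k,
                "n_nodes": r.n_nodes,
                "n_clusters": r.n_clusters,
                "mean_pair_mismatch": r.match.mean_pair_mismatch,
                "overall_mismatch": r.match.overall_mismatch,
                "percolated": r.percolated,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class OptimalSolution:
    """The accepted optimized web."""

    threshold_r: float
    threshold_p: float
    k_star: int
    web: SymptomGraph
    ncs: Partition
    pcs: Partition
    match: MatchResult
    record: SweepRecord


def sweep(
    scores: pd.DataFrame | None = None,
    ks: Sequence[int] = tuple(range(5, 11)),
    n_boot: int = 10_000,
    seed: int = 0,
    corr: BootCorrelation | None = None,
) -> SweepResult:
    """Run the full incremental-pruning sweep.

    Either ``scores`` (imputed, complete) or a precomputed ``corr`` must be
    given. Community detection runs at every edge removal; candidate PCAs
    are re-fit only when the surviving item set changed since the last fit.
    """
    if corr is None:
        if scores is None:
            raise ValueError("provide scores or a precomputed correlation")
        corr = bootstrap_correlation_matrix(scores, n_boot=n_boot, seed=seed)
    ks = tuple(sorted(set(int(k) for k in ks)))
    if not ks:
        raise ValueError("ks must be non-empty")

    base = build_graph(corr)
    schedule = prune_schedule(base)
    g = base.graph.copy()

    records: list[SweepRecord] = []
    solutions: dict[int, ComponentSolution] = {}
    fitted_for: frozenset[str] = frozenset()

    for step in schedule:
        if g.has_edge(*step.edge):
            g.remove_edge(*step.edge)
        g.remove_nodes_from([n for n in step.edge if n in g and g.degree[n] == 0])
        alive = frozenset(n for n, d in g.degree if d > 0)
        if len(alive) < 2:
            break
        sg = SymptomGraph(g.subgraph(alive).copy(), threshold=step.threshold_r)
        ncs_result = greedy_modularity_partition(sg)
        ncs = ncs_result.partition

        if alive != fitted_for:
            sub = corr.r.loc[sorted(alive), sorted(alive)]
            solutions = {}
            for k in ks:
                if k > len(alive):
                    continue
                try:
                    solutions[k] = fit_components(sub, k)
                except ValueError:
                    logger.debug("skipping k=%d at step %d (rank)", k, step.index)
            fitted_for = alive

        for k, sol in sorted(solutions.items()):
            match = match_partitions(ncs, sol.assignment)
            records.append(
                SweepRecord(
                    step=step,
                    k=k,
                    ncs=ncs,
                    pcs=sol.assignment,
                    match=match,
                    n_nodes=len(alive),
                    n_clusters=ncs.n_modules,
                    percolated=step.n_components > 1,
                )
            )
    return SweepResult(records, corr, base, schedule, ks)


def select_optimum(
    sweep_result: SweepResult,
    min_fraction: float = 0.8,
) -> OptimalSolution:
    """Pick the accepted optimum from a sweep.

    Admissible records are unpercolated and retain at least
    ``ceil(min_fraction * total items)`` nodes; among them the smallest
    mean per-pair mismatch wins, ties broken by more nodes, then lower
    threshold, then lower k.
    """
    records = sweep_result.records
    if not records:
        raise ValueError("empty sweep")
    n_total = len(sweep_result.base_graph.nodes)
    floor = ceil(min_fraction * n_total)
    admissible = [r for r in records if not r.percolated and r.n_nodes >= floor]
    if not admissible:
        raise ValueError(
            f"no unpercolated record retains >= {floor} of {n_total} items; "
            "lower min_fraction"
        )
    best = min(
        admissible,
        key=lambda r: (
            r.match.mean_pair_mismatch,
            -r.n_nodes,
            r.threshold_r,
            r.k,
        ),
    )
    from .graph import apply_steps  # local import to avoid cycle at module load

    web = apply_steps(sweep_result.base_graph, sweep_result.schedule, best.step.index)
    return OptimalSolution(
        threshold_r=best.threshold_r,
        threshold_p=best.threshold_p,
        k_star=best.k,
        web=web,
        ncs=best.ncs,
        pcs=best.pcs,
        match=best.match,
        record=best,
    )


def global_minimum(sweep_result: SweepResult) -> SweepRecord:
    """The unconstrained minimum-mismatch record (percolated ones included)."""
    return min(
        sweep_result.records,
        key=lambda r: (r.match.mean_pair_mismatch, -r.n_nodes, r.threshold_r, r.k),
    )


@dataclass(frozen=True)
class DropoffDiagnostics:
    """Per-item drop-off thresholds and their covariate correlations."""

    table: pd.DataFrame = field(repr=False)
    corr_zero_fraction: tuple[float, float]  # (r, p)
    corr_n_missing: tuple[float, float]


def dropoff_diagnostics(
    sweep_result: SweepResult,
    scores: pd.DataFrame,
    optimum: OptimalSolution | None = None,
) -> DropoffDiagnostics:
    """Relate each item's drop-off threshold to its rarity and missingness.

    An item's drop-off threshold is the |r| at which it lost its last edge
    during pruning. Items still in the accepted web are censored and
    contribute their weakest retained link's |r| instead. Covariates come
    from the raw (pre-imputation) scores: fraction of zero scores and
    missing-cell count. Pearson correlations are computed across items.

    Sign convention: the reported correlation is between the drop-off
    threshold and the zero-score fraction, so rarity-driven early drop-off
    appears as a *negative* value (rare items have high zero fractions and
    low drop-off thresholds); the equivalent association with frequency of
    occurrence has the opposite sign.
    """
    drop_thr: dict[str, float] = {}
    for step in sweep_result.schedule:
        for item in step.dropped_items:
            drop_thr.setdefault(item, step.threshold_r)

    survivors: dict[str, float] = {}
    if optimum is not None:
        g = optimum.web.graph
        for n in g.nodes:
            survivors[n] = min(abs(d["weight"]) for _, _, d in g.edges(n, data=True))

    rows = []
    for item in sweep_result.base_graph.nodes:
        col = scores[item]
        rows.append(
            {
                "item": item,
                "dropoff_r": survivors.get(item, drop_thr.get(item, np.nan)),
                "censored": item in survivors,
                "zero_fraction": float((col == 0).sum() / col.notna().sum()),
                "n_missing": int(col.isna().sum()),
            }
        )
    table = pd.DataFrame(rows).set_index("item")

    ok = table["dropoff_r"].notna()
    cz = pearsonr(table.loc[ok, "dropoff_r"], table.loc[ok, "zero_fraction"])
    if table.loc[ok, "n_missing"].nunique() > 1:
        cm = pearsonr(table.loc[ok, "dropoff_r"], table.loc[ok, "n_missing"])
        corr_missing = (float(cm.statistic), float(cm.pvalue))
    else:
        corr_missing = (float("nan"), float("nan"))
    return DropoffDiagnostics(
        table=table,
        corr_zero_fraction=(float(cz.statistic), float(cz.pvalue)),
        corr_n_missing=corr_missing,
    )
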
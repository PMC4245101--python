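"""Model/Results front end for the symptom-web pipeline.

:class:`PsychopathologyWeb` holds a validated patients x items ordinal
score matrix; :meth:`PsychopathologyWeb.fit` runs the full procedure
(impute, bootstrap the correlation matrix, sweep pruning thresholds while
matching network communities against candidate component structures,
select the accepted optimum, and characterize it with weighted network
metrics, bridge/core classification, small-worldness and group
comparisons) and returns a :class:`PsychopathologyWebResults` carrying all
stage outputs, a ``summary()`` table and exporters.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .components import scree
from .metrics import (
    SmallWorldResult,
    bridge_core_summary,
    compare_groups,
    node_metrics,
    small_worldness,
)
from .optimize import (
    DropoffDiagnostics,
    OptimalSolution,
    SweepResult,
    dropoff_diagnostics,
    global_minimum,
    select_optimum,
    sweep,
)
from .preprocess import (
    AdequacyStats,
    BootCorrelation,
    adequacy,
    bootstrap_correlation_matrix,
    impute_column_means,
    read_scores,
)

logger = logging.getLogger(__name__)

__all__ = ["PsychopathologyWeb", "PsychopathologyWebResults"]


class PsychopathologyWeb:
    """Symptom co-occurrence network model of an ordinal score matrix.

    Parameters
    ----------
    scores : DataFrame
        Patients x items integer scores; NaN marks missing cells.
    score_range : (min, max)
        Admissible score range, default (0, 6).
    """

    def __init__(self, scores: pd.DataFrame, score_range: tuple[int, int] = (0, 6)):
        lo, hi = score_range
        vals = scores.to_numpy(dtype=float)
        finite = vals[~pd.isna(vals)]
        if finite.size and ((finite < lo) | (finite > hi)).any():
            raise ValueError(f"scores outside [{lo}, {hi}]")
        if scores.columns.has_duplicates:
            raise ValueError("duplicate item labels")
        empty = scores.columns[scores.isna().all(axis=0)]
        if len(empty):
            logger.info("dropping %d all-missing item(s): %s", len(empty), list(empty))
            scores = scores.drop(columns=list(empty))
        self.scores = scores
        self.score_range = score_range
        self.imputed = impute_column_means(scores)

    @classmethod
    def from_csv(cls, path, score_range: tuple[int, int] = (0, 6)) -> "PsychopathologyWeb":
        return cls(read_scores(path, score_range), score_range)

    @property
    def n_patients(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def fit(
        self,
        n_boot: int = 10_000,
        seed: int = 0,
        ks: Sequence[int] = tuple(range(5, 11)),
        min_fraction: float = 0.8,
        n_random: int = 100,
    ) -> "PsychopathologyWebResults":
        """Run the full pipeline and return a results object."""
        t0 = time.perf_counter()
        logger.info("adequacy statistics (plain correlation matrix)")
        adeq = adequacy(self.imputed)
        logger.info("bootstrapping correlation matrix: n_boot=%d seed=%d", n_boot, seed)
        corr = bootstrap_correlation_matrix(self.imputed, n_boot=n_boot, seed=seed)
        logger.info("sweeping pruning thresholds, ks=%s", list(ks))
        sweep_result = sweep(corr=corr, ks=ks)
        logger.info("selecting optimum (min_fraction=%.2f)", min_fraction)
        optimum = select_optimum(sweep_result, min_fraction=min_fraction)
        metrics = node_metrics(optimum.web, optimum.ncs)
        sw = small_worldness(optimum.web, n_random=n_random, seed=seed)
        comparisons = compare_groups(metrics)
        diagnostics = dropoff_diagnostics(sweep_result, self.scores, optimum)
        logger.info("fit complete in %.1f s", time.perf_counter() - t0)
        return PsychopathologyWebResults(
            model=self,
            params={
                "n_boot": n_boot,
                "seed": seed,
                "ks": [int(k) for k in ks],
                "min_fraction": min_fraction,
                "n_random": n_random,
            },
            adequacy=adeq,
            corr=corr,
            sweep=sweep_result,
            optimum=optimum,
            metrics=metrics,
            small_world=sw,
            comparisons=comparisons,
            diagnostics=diagnostics,
        )


@dataclass
class PsychopathologyWebResults:
    """Fitted symptom web with all stage outputs."""

    model: PsychopathologyWeb
    params: dict
    adequacy: AdequacyStats
    corr: BootCorrelation
    sweep: SweepResult
    optimum: OptimalSolution
    metrics: pd.DataFrame = field(repr=False)
    small_world: SmallWorldResult
    comparisons: list
    diagnostics: DropoffDiagnostics

    @property
    def global_minimum(self):
        return global_minimum(self.sweep)

    def summary(self) -> str:
        """Human-readable results table."""
        opt = self.optimum
        bc = bridge_core_summary(self.metrics)
        gm = self.global_minimum
        lines = [
            "Psychopathology Web Results",
            "=" * 64,
            f"patients: {self.model.n_patients:>5d}    items: {self.model.n_items}",
            f"bootstrap: n_boot={self.params['n_boot']}  seed={self.params['seed']}",
            f"KMO: {self.adequacy.kmo:.3f}    Bartlett chi2: "
            f"{self.adequacy.bartlett_chi2:.1f} (df={self.adequacy.bartlett_df}, "
            f"p={self.adequacy.bartlett_p:.2e})",
            "-" * 64,
            f"accepted optimum: k*={opt.k_star}  |r|>={opt.threshold_r:.4f}  "
            f"(p={opt.threshold_p:.2e})",
            f"surviving nodes: {opt.record.n_nodes}   clusters: {opt.record.n_clusters}",
            f"mean per-pair mismatch: {100 * opt.match.mean_pair_mismatch:.1f}%   "
            f"disputed items: {len(opt.match.disputed_items)}/{opt.match.n_items} "
            f"({100 * opt.match.overall_mismatch:.1f}%)",
            "per-pair mismatch: "
            + "  ".join(
                f"{c}:{100 * v:.1f}%"
                for c, v in sorted(opt.match.per_pair_mismatch.items(), key=lambda x: str(x[0]))
            ),
            f"global (unconstrained) minimum: {100 * gm.match.mean_pair_mismatch:.1f}% "
            f"at |r|={gm.threshold_r:.4f}, k={gm.k}, {gm.n_nodes} nodes"
            + ("  [percolated]" if gm.percolated else ""),
            "-" * 64,
            f"bridge symptoms: {bc['n_bridge']} ({bc['pct_bridge']:.0f}%)   "
            f"core symptoms: {bc['n_core']} ({bc['pct_core']:.0f}%)   "
            f"max external clusters: {bc['max_external_clusters']}",
            f"small-worldness: S={self.small_world.s:.2f}  "
            f"(C={self.small_world.c_obs:.3f}, L={self.small_world.l_obs:.2f}, "
            f"{self.small_world.n_random} random references)",
            f"drop-off vs zero-score fraction: r={self.diagnostics.corr_zero_fraction[0]:.3f} "
            f"(p={self.diagnostics.corr_zero_fraction[1]:.3f})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable run summary (deterministic for a fixed seed)."""
        opt = self.optimum
        bc = bridge_core_summary(self.metrics)
        gm = self.global_minimum
        return {
            "version": __version__,
            "params": self.params,
            "n_patients": self.model.n_patients,
            "n_items": self.model.n_items,
            "adequacy": {
                "kmo": round(self.adequacy.kmo, 10),
                "bartlett_chi2": round(self.adequacy.bartlett_chi2, 6),
                "bartlett_df": self.adequacy.bartlett_df,
                "bartlett_p": self.adequacy.bartlett_p,
            },
            "optimum": {
                "k_star": opt.k_star,
                "threshold_r": round(opt.threshold_r, 10),
                "threshold_p": opt.threshold_p,
                "n_nodes": opt.record.n_nodes,
                "n_clusters": opt.record.n_clusters,
                "mean_pair_mismatch": round(opt.match.mean_pair_mismatch, 10),
                "overall_mismatch": round(opt.match.overall_mismatch, 10),
                "n_disputed": len(opt.match.disputed_items),
                "disputed_items": sorted(opt.match.disputed_items),
                "per_pair_mismatch": {
                    str(c): round(v, 10)
                    for c, v in sorted(
                        opt.match.per_pair_mismatch.items(), key=lambda x: str(x[0])
                    )
                },
                "clusters": {
                    str(m): sorted(items) for m, items in sorted(
                        opt.ncs.modules.items(), key=lambda x: str(x[0])
                    )
                },
            },
            "global_minimum": {
                "k": gm.k,
                "threshold_r": round(gm.threshold_r, 10),
                "n_nodes": gm.n_nodes,
                "mean_pair_mismatch": round(gm.match.mean_pair_mismatch, 10),
                "percolated": gm.percolated,
            },
            "bridge_core": bc,
            "small_world": {
                "s": round(self.small_world.s, 10),
                "c_obs": round(self.small_world.c_obs, 10),
                "l_obs": round(self.small_world.l_obs, 10),
                "c_rand": round(self.small_world.c_rand, 10),
                "l_rand": round(self.small_world.l_rand, 10),
            },
            "dropoff": {
                "corr_zero_fraction": [
                    round(self.diagnostics.corr_zero_fraction[0], 10),
                    self.diagnostics.corr_zero_fraction[1],
                ],
                "corr_n_missing": list(self.diagnostics.corr_n_missing),
            },
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def save_outputs(self, outdir) -> dict[str, Path]:
        """Write all module outputs (tables, graphs, plots) to a directory."""
        import matplotlib.pyplot as plt

        from .plots import plot_mismatch, plot_pruning, plot_scree

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        paths["summary"] = out / "summary.json"
        self.to_json(paths["summary"])

        paths["correlation"] = out / "correlation.csv"
        self.corr.to_csv(paths["correlation"], out / "correlation_p.csv")
        paths["edges"] = out / "web_edges.csv"
        self.optimum.web.to_edge_csv(paths["edges"])
        paths["graphml"] = out / "web.graphml"
        g = self.optimum.web.copy()
        for item, row in self.metrics.iterrows():
            g.graph.nodes[item].update(
                cluster=str(row["cluster"]),
                status=row["status"],
                ln_w_D=float(row["ln_w_D"]),
                ln_w_BS=float(row["ln_w_BS"]),
                ln_w_CS=float(row["ln_w_CS"]),
            )
        g.to_graphml(paths["graphml"])
        paths["ncs"] = out / "network_clusters.csv"
        self.optimum.ncs.to_csv(paths["ncs"])
        paths["pcs"] = out / "component_assignment.csv"
        self.optimum.pcs.to_csv(paths["pcs"])
        paths["trace"] = out / "sweep_trace.csv"
        trace = self.sweep.trace_frame()
        trace.to_csv(paths["trace"], index=False)
        paths["metrics"] = out / "node_metrics.csv"
        self.metrics.to_csv(paths["metrics"])
        paths["dropoff"] = out / "dropoff_diagnostics.csv"
        self.diagnostics.table.to_csv(paths["dropoff"])

        for name, plot, arg in [
            ("scree", plot_scree, scree(self.corr)),
            ("pruning", plot_pruning, trace),
            ("mismatch", plot_mismatch, trace),
        ]:
            ax = plot(arg)
            paths[name] = out / f"{name}.png"
            ax.figure.savefig(paths[name], dpi=120)
            plt.close(ax.figure)
        return paths
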
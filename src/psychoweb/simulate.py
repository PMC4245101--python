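"""Synthetic ordinal symptom-score matrices with planted modular structure.

The generator emulates the salient features of a clinician-rated symptom
inventory administered to a heterogeneous patient sample: a handful of
latent symptom clusters of unequal size, a few "bridge" items that load on
two clusters at once, zero-inflated rare symptoms, a small completely-random
missingness rate, and discretization of the underlying continuous severity
to a 0..6 ordinal scale.

Model: each patient draws one standard-normal latent severity per cluster;
item i in cluster c has continuous value

    y_i = lambda * f_c (+ lambda2 * f_c2 for bridge items) + eps,
    eps ~ N(0, noise_sd^2)

which is then cut into ``n_levels`` equal-probability bins by the sample
quantiles of y_i, so every score level is populated regardless of the item's
marginal scale. Zero inflation overwrites the discretized score with 0 with
per-item probability ``rarity``; missingness blanks cells MCAR afterwards.

All random draws (factors, noise, rarity mask, missing mask) are made in a
fixed order that does not depend on the loadings, so the same seed yields
the same latent sample across loading settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition import Partition

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_scores"]


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of the planted-cluster ordinal score generator.

    Defaults mirror the study design the generator emulates: 192 patients,
    six symptom clusters of unequal size summing to 63 scored items, scores
    on a 0-6 scale, rare missingness (~0.6% of cells).
    """

    n_patients: int = 192
    cluster_sizes: tuple[int, ...] = (19, 12, 10, 9, 7, 6)  # six unequal clusters, 63 items
    within_loading: float = 0.8
    bridge_items: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = 0.6
    rarity: float | tuple[float, ...] = 0.0
    missing_rate: float = 0.006
    n_levels: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not self.cluster_sizes or any(s <= 0 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be non-empty positive counts")
        if not 0.0 <= self.within_loading <= 1.0:
            raise ValueError("within_loading must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for r in np.atleast_1d(np.asarray(self.rarity, dtype=float)):
            if not 0.0 <= r < 1.0:
                raise ValueError("rarity must lie in [0, 1)")
        if self.n_levels < 2:
            raise ValueError("n_levels must be at least 2")
        n_items = self.n_items
        for item, cluster, loading in self.bridge_items:
            if not 0 <= item < n_items:
                raise ValueError(f"bridge item index {item} out of range")
            if not 0 <= cluster < len(self.cluster_sizes):
                raise ValueError(f"bridge cluster index {cluster} out of range")
            if cluster == self.primary_cluster_of(item):
                raise ValueError("bridge item must reference a second, distinct cluster")
            if not 0.0 <= loading <= 1.0:
                raise ValueError("bridge loading must lie in [0, 1]")

    @property
    def n_items(self) -> int:
        return int(sum(self.cluster_sizes))

    def primary_cluster_of(self, item: int) -> int:
        edges = np.cumsum(self.cluster_sizes)
        return int(np.searchsorted(edges, item, side="right"))

    @property
    def item_labels(self) -> list[str]:
        width = max(2, len(str(self.n_items)))
        return [f"it{i + 1:0{width}d}" for i in range(self.n_items)]


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated score matrix plus its ground truth."""

    scores: pd.DataFrame  # patients x items, NaN = missing
    planted_partition: Partition
    latent_factors: np.ndarray = field(repr=False)  # patients x clusters
    continuous: np.ndarray = field(repr=False)  # patients x items, pre-discretization

    def write_scores_csv(self, path) -> None:
        out = self.scores.copy()
        out.index.name = "patient"
        # integers with empty cells for missing
        out.to_csv(path, float_format="%.0f", na_rep="")

    def write_partition_csv(self, path) -> None:
        self.planted_partition.to_csv(path)


def _discretize_by_quantiles(y: np.ndarray, n_levels: int) -> np.ndarray:
    """Cut each column into equal-probability bins via its sample quantiles."""
    qs = np.quantile(y, np.arange(1, n_levels) / n_levels, axis=0)  # (n_levels-1, items)
    scores = np.empty(y.shape, dtype=np.int64)
    for j in range(y.shape[1]):
        scores[:, j] = np.searchsorted(qs[:, j], y[:, j], side="left")
    return scores


def generate_scores(config: SimulationConfig) -> SyntheticDataset:
    """Generate an ordinal patients x items score matrix with planted clusters.

    Returns the scores together with the planted item partition and the
    latent per-patient cluster severities.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n_patients, len(config.cluster_sizes)
    m = config.n_items

    # fixed draw order, independent of loadings (see module docstring)
    factors = rng.standard_normal((n, k))
    noise = rng.standard_normal((n, m)) * config.noise_sd
    rarity = np.broadcast_to(np.atleast_1d(np.asarray(config.rarity, float)), (m,))
    rare_mask = rng.random((n, m)) < rarity[None, :]
    miss_mask = rng.random((n, m)) < config.missing_rate

    primary = np.array([config.primary_cluster_of(i) for i in range(m)])
    y = config.within_loading * factors[:, primary] + noise
    for item, cluster, loading in config.bridge_items:
        y[:, item] += loading * factors[:, cluster]

    scores = _discretize_by_quantiles(y, config.n_levels)
    scores[rare_mask] = 0

    values = scores.astype(float)
    values[miss_mask] = np.nan

    labels = config.item_labels
    frame = pd.DataFrame(
        values,
        index=[f"p{i + 1:04d}" for i in range(n)],
        columns=labels,
    )
    planted = Partition({labels[i]: int(primary[i]) + 1 for i in range(m)})
    return SyntheticDataset(frame, planted, factors, y)
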
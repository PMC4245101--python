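"""Publication-shaped plots: scree, pruning, and mismatch curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_scree", "plot_pruning", "plot_mismatch"]


def plot_scree(eigenvalues: np.ndarray, ax=None):
    """Descending eigenvalue spectrum of the correlation matrix."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(1, len(eigenvalues) + 1)
    ax.plot(x, eigenvalues, "o-", ms=3)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax.set_title("Scree plot")
    return ax


def plot_pruning(trace: pd.DataFrame, ax=None):
    """Cluster count against the |r| pruning threshold."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    one_k = trace.drop_duplicates(subset="step")
    ax.step(one_k["threshold_r"], one_k["n_clusters"], where="post")
    ax.set_xlabel("|r| threshold")
    ax.set_ylabel("number of clusters")
    ax.set_title("Incremental pruning plot")
    return ax


def plot_mismatch(trace: pd.DataFrame, ax=None):
    """Mean per-pair mismatch against the threshold, one curve per k."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for k, sub in trace.groupby("k"):
        ax.plot(sub["threshold_r"], sub["mean_pair_mismatch"], label=f"{k}-PCS", lw=0.9)
    ax.set_xlabel("|r| threshold")
    ax.set_ylabel("mean per-pair mismatch")
    ax.set_title("NCS-to-PCS matching")
    ax.legend(fontsize=8)
    return ax
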
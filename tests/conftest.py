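import networkx as nx
import numpy as np
import pandas as pd
import pytest

from psychoweb import BootCorrelation, SimulationConfig, SymptomGraph, generate_scores


def make_graph(edges):
    """SymptomGraph from (u, v, weight) triples; p defaults to 0.01."""
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=float(w), p=0.01)
    return SymptomGraph(g)


def corr_from_data(values, labels=None, p=0.5):
    """BootCorrelation wrapper around a plain correlation of a data matrix."""
    values = np.asarray(values, dtype=float)
    labels = labels or [f"it{i + 1:02d}" for i in range(values.shape[1])]
    r = np.corrcoef(values, rowvar=False)
    pm = np.full_like(r, p)
    np.fill_diagonal(pm, 1e-4)
    return BootCorrelation(
        r=pd.DataFrame(r, index=labels, columns=labels),
        p=pd.DataFrame(pm, index=labels, columns=labels),
        n_boot=1,
        seed=0,
    )


def block_correlation(block_sizes, within, between=0.0, labels=None):
    """Exact block-structured correlation matrix as a BootCorrelation."""
    m = sum(block_sizes)
    labels = labels or [f"it{i + 1:02d}" for i in range(m)]
    r = np.full((m, m), between, dtype=float)
    start = 0
    for size in block_sizes:
        r[start : start + size, start : start + size] = within
        start += size
    np.fill_diagonal(r, 1.0)
    pm = np.full((m, m), 1e-3)
    return BootCorrelation(
        r=pd.DataFrame(r, index=labels, columns=labels),
        p=pd.DataFrame(pm, index=labels, columns=labels),
        n_boot=1,
        seed=0,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong 6-cluster synthetic dataset used by several pipeline tests."""
    cfg = SimulationConfig(
        n_patients=500,
        cluster_sizes=(8, 8, 8, 8, 8, 8),
        within_loading=0.8,
        noise_sd=0.6,
        missing_rate=0.01,
        seed=11,
    )
    return generate_scores(cfg)


@pytest.fixture(scope="session")
def small_scores():
    """Small, quick synthetic score matrix (no zero inflation)."""
    cfg = SimulationConfig(
        n_patients=150,
        cluster_sizes=(6, 5, 5),
        within_loading=0.7,
        noise_sd=0.7,
        missing_rate=0.02,
        seed=5,
    )
    return generate_scores(cfg)
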
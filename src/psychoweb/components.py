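"""Confirmatory principal components with Varimax rotation and forced choice.

A candidate k-component structure is extracted directly from the
(bootstrapped) correlation matrix: the k leading eigenvectors scaled by the
square roots of their eigenvalues form the unrotated loading matrix, which
is then rotated by the Varimax criterion (orthogonal, with Kaiser row
normalization). Each item is finally assigned to the single component on
which it has the largest absolute rotated loading — the forced-choice
partition that is matched against network community structures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .partition import Partition
from .preprocess import BootCorrelation

__all__ = ["ComponentSolution", "varimax", "fit_components", "scree"]


@dataclass(frozen=True)
class ComponentSolution:
    """Rotated k-component solution with its forced-choice partition."""

    k: int
    loadings: pd.DataFrame  # items x k, Varimax-rotated
    eigenvalues: np.ndarray  # k leading eigenvalues, descending
    assignment: Partition

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Maximizes the variance of squared loadings within each column over
    orthogonal rotations, by the standard pairwise-SVD iteration. With
    ``kaiser_normalize`` rows are scaled to unit communality during the
    rotation and rescaled afterwards.

    Returns ``(rotated, rotation)`` with ``rotated = loadings @ rotation``
    (up to Kaiser scaling) and ``rotation`` orthonormal.
    """
    L = np.asarray(loadings, dtype=float).copy()
    n, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.ones(n)
    if kaiser_normalize:
        h = np.sqrt((L**2).sum(axis=1))
        h[h == 0] = 1.0
        L = L / h[:, None]

    rotation = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ rotation
        tmp = Lr**3 - Lr * (Lr**2).sum(axis=0) / n
        u, s, vt = np.linalg.svd(L.T @ tmp)
        rotation = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new

    rotated = (L @ rotation) * h[:, None]
    return rotated, rotation


def fit_components(corr: BootCorrelation | pd.DataFrame, k: int) -> ComponentSolution:
    """Fit a k-component solution to a correlation matrix.

    Eigen-decomposes the matrix, keeps the k leading components as
    loadings (eigenvector * sqrt(eigenvalue)), Varimax-rotates them, and
    assigns each item to the component with its largest absolute rotated
    loading (ties broken toward the lowest component index).
    """
    r = corr.r if isinstance(corr, BootCorrelation) else corr
    items = list(r.columns)
    a = r.to_numpy()
    m = a.shape[0]
    if not 1 <= k <= m:
        raise ValueError(f"k={k} outside [1, {m}]")
    evals, evecs = np.linalg.eigh((a + a.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > 1e-10).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    lead = evals[:k]
    load = evecs[:, :k] * np.sqrt(lead)[None, :]

    rotated, _ = varimax(load)
    # deterministic sign: make each column's largest-|.| loading positive
    for j in range(k):
        i = int(np.argmax(np.abs(rotated[:, j])))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]

    # forced choice on absolute loadings; np.argmax takes the first maximum,
    # which is the lowest component index on ties
    choice = np.argmax(np.abs(rotated), axis=1)
    assignment = Partition({items[i]: int(choice[i]) + 1 for i in range(m)})

    cols = [f"PC{j + 1}" for j in range(k)]
    return ComponentSolution(
        k=k,
        loadings=pd.DataFrame(rotated, index=items, columns=cols),
        eigenvalues=lead,
        assignment=assignment,
    )


def scree(corr: BootCorrelation | pd.DataFrame) -> np.ndarray:
    """Full descending eigenvalue spectrum of the correlation matrix."""
    r = corr.r if isinstance(corr, BootCorrelation) else corr
    a = r.to_numpy()
    evals = np.linalg.eigvalsh((a + a.T) / 2.0)
    return evals[::-1]
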
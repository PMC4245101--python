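"""Score-matrix ingestion, imputation, bootstrapped correlations, adequacy stats.

The raw input is a rectangular patients x items table of ordinal symptom
scores (0-6 by default) with occasional missing cells. This module reads
and validates it, drops items with no recorded scores at all, imputes
missing cells with column means, and estimates the item-item Pearson
correlation matrix by bootstrapping patients with replacement.

The bootstrap point estimate of each pairwise correlation is the mean of
the replicate correlations; its significance is a two-sided sign test, the
fraction of replicates on which the correlation crosses zero:

    p_ij = max(1/n_boot, 2 * min(P(r*_ij <= 0), P(r*_ij >= 0)))

which is monotone in |r| on any fixed pair. Sampling-adequacy statistics
(overall Kaiser-Meyer-Olkin measure and Bartlett's test of sphericity) are
computed on the plain, pre-bootstrap correlation matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AdequacyStats",
    "BootCorrelation",
    "read_scores",
    "impute_column_means",
    "plain_correlation",
    "bootstrap_correlation_matrix",
    "kmo",
    "bartlett_sphericity",
    "adequacy",
]


@dataclass(frozen=True)
class BootCorrelation:
    """Bootstrap-estimated correlation matrix with sign-test significances."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        rv = self.r.to_numpy()
        if rv.shape[0] != rv.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(rv, rv.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(rv), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")

    @property
    def items(self) -> list[str]:
        return list(self.r.columns)

    def to_csv(self, r_path, p_path=None) -> None:
        self.r.to_csv(r_path)
        if p_path is not None:
            self.p.to_csv(p_path)


@dataclass(frozen=True)
class AdequacyStats:
    """Sampling adequacy of a correlation matrix prior to dimension reduction."""

    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float


def read_scores(path, score_range: tuple[int, int] = (0, 6)) -> pd.DataFrame:
    """Read a delimited patients x items score table.

    First column = patient id, header row = item labels, empty cell =
    missing. Items whose column holds no recorded score at all are dropped
    (logged); out-of-range or non-integer scores raise ``ValueError`` naming
    the offending cell.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    labels = header[1:]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate item labels: {sorted(dupes)}")

    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = labels  # undo any pandas mangling
    if df.index.has_duplicates:
        raise ValueError("duplicate patient ids")
    df = df.astype(float)

    lo, hi = score_range
    values = df.to_numpy()
    bad = np.zeros(values.shape, dtype=bool)
    with np.errstate(invalid="ignore"):
        finite = np.isfinite(values)
        bad[finite] = (
            (values[finite] < lo)
            | (values[finite] > hi)
            | (values[finite] != np.round(values[finite]))
        )
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"score {values[i, j]!r} at patient {df.index[i]!r}, item "
            f"{df.columns[j]!r} outside integer range [{lo}, {hi}]"
        )

    empty = [c for c in df.columns if df[c].isna().all()]
    if empty:
        logger.info("dropping %d item(s) with no recorded scores: %s", len(empty), empty)
        df = df.drop(columns=empty)
    return df


def impute_column_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Replace each missing cell by its item's mean over recorded scores.

    Imputed values are kept real-valued so column means are conserved
    exactly; non-missing cells are untouched.
    """
    if scores.isna().all(axis=0).any():
        bad = scores.columns[scores.isna().all(axis=0)].tolist()
        raise ValueError(f"all-missing item(s), drop them first: {bad}")
    return scores.fillna(scores.mean(axis=0))


def _check_complete(scores: pd.DataFrame) -> np.ndarray:
    values = scores.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("scores contain missing values; impute first")
    return values


def plain_correlation(scores: pd.DataFrame) -> pd.DataFrame:
    """Plain (non-bootstrap) Pearson correlation matrix of the items."""
    values = _check_complete(scores)
    sd = values.std(axis=0)
    if (sd == 0).any():
        bad = scores.columns[sd == 0].tolist()
        raise ValueError(f"constant item(s), correlation undefined: {bad}")
    r = np.corrcoef(values, rowvar=False)
    return pd.DataFrame(r, index=scores.columns, columns=scores.columns)


def bootstrap_correlation_matrix(
    scores: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    batch_size: int = 128,
) -> BootCorrelation:
    """Bootstrap the item-item Pearson matrix by resampling patients.

    Each replicate resamples the patient rows with replacement (one index
    draw per replicate for the whole matrix, so replicate matrices are
    internally consistent) and computes the full Pearson matrix. The
    returned estimate is the element-wise mean over replicates; pairs
    degenerate in a replicate (an item constant in that resample) are
    skipped for that replicate. p is the two-sided sign test described in
    the module docstring.
    """
    values = _check_complete(scores)
    n, m = values.shape
    if n < 3:
        raise ValueError("need at least 3 patients to bootstrap correlations")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if (values.std(axis=0) == 0).any():
        bad = scores.columns[values.std(axis=0) == 0].tolist()
        raise ValueError(f"constant item(s), correlation undefined: {bad}")

    rng = np.random.default_rng(seed)
    r_sum = np.zeros((m, m))
    n_valid = np.zeros((m, m), dtype=np.int64)
    n_nonpos = np.zeros((m, m), dtype=np.int64)
    n_nonneg = np.zeros((m, m), dtype=np.int64)

    done = 0
    while done < n_boot:
        b = min(batch_size, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        x = values[idx]  # (b, n, m)
        xc = x - x.mean(axis=1, keepdims=True)
        cov = np.einsum("bni,bnj->bij", xc, xc)
        sd = np.sqrt(np.einsum("bii->bi", cov))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = cov / (sd[:, :, None] * sd[:, None, :])
        ok = np.isfinite(r)
        np.clip(r, -1.0, 1.0, out=r, where=ok)
        r_sum += np.where(ok, r, 0.0).sum(axis=0)
        n_valid += ok.sum(axis=0)
        n_nonpos += (ok & (r <= 0)).sum(axis=0)
        n_nonneg += (ok & (r >= 0)).sum(axis=0)
        done += b

    if (n_valid == 0).any():
        raise ValueError("some item pair was degenerate in every bootstrap replicate")
    r_hat = r_sum / n_valid
    r_hat = (r_hat + r_hat.T) / 2.0
    np.fill_diagonal(r_hat, 1.0)

    with np.errstate(invalid="ignore"):
        frac_nonpos = n_nonpos / n_valid
        frac_nonneg = n_nonneg / n_valid
    p = 2.0 * np.minimum(frac_nonpos, frac_nonneg)
    p = np.clip(p, 1.0 / n_boot, 1.0)
    p = (p + p.T) / 2.0
    np.fill_diagonal(p, 1.0 / n_boot)

    cols = scores.columns
    return BootCorrelation(
        r=pd.DataFrame(r_hat, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n_boot=n_boot,
        seed=seed,
    )


def kmo(scores: pd.DataFrame) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum q_ij^2) over i != j, where q are
    the anti-image partial correlations obtained from the inverse of the
    plain correlation matrix. A near-singular matrix is ridge-regularized
    by adding 1e-8 to the diagonal (logged).
    """
    r = plain_correlation(scores).to_numpy()
    try:
        inv = np.linalg.inv(r)
    except np.linalg.LinAlgError:
        logger.warning("correlation matrix singular; ridge-regularizing diagonal by 1e-8")
        inv = np.linalg.inv(r + 1e-8 * np.eye(r.shape[0]))
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    q = -inv / d
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    q2 = (q[off] ** 2).sum()
    return float(r2 / (r2 + q2))


def bartlett_sphericity(scores: pd.DataFrame) -> AdequacyStats:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2m + 5)/6) * ln det(R) with m items and n patients,
    df = m(m-1)/2. Warns when n is not comfortably larger than m.
    """
    r = plain_correlation(scores).to_numpy()
    n, m = scores.shape
    if n <= m:
        logger.warning("only %d patients for %d items; sphericity test unreliable", n, m)
    sign, logdet = np.linalg.slogdet(r)
    if sign <= 0:
        raise np.linalg.LinAlgError("correlation matrix has non-positive determinant")
    chi2 = -(n - 1 - (2 * m + 5) / 6.0) * logdet
    df = m * (m - 1) // 2
    p = float(stats.chi2.sf(chi2, df))
    return AdequacyStats(kmo=kmo(scores), bartlett_chi2=float(chi2), bartlett_df=df, bartlett_p=p)


def adequacy(scores: pd.DataFrame) -> AdequacyStats:
    """KMO and Bartlett sphericity of the plain correlation matrix."""
    return bartlett_sphericity(scores)
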
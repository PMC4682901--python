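"""Gene-expression correlation screen against tumor eccentricity (SED).

Each gene's normalized FPKM profile across samples is correlated with the
per-sample SED value (Pearson r, two-sided t-based p on n-2 df).  Candidate
genes must pass all three filters, with strict inequalities:

* ``p < 0.01`` (significance of the correlation),
* ``mean > 10`` FPKM (expressed at a usable level),
* ``CV > 1`` (coefficient of variation; varies enough to carry signal).

No multiple-testing correction is applied to the filter; Benjamini-Hochberg
q-values are reported as an informational column.  Output rows are
partitioned by correlation sign and sorted ascending by r within each
partition (strongest negative correlation first, weakest positive last).
Correlations are computed on the FPKM scale by default; ``log_transform``
switches to log2(FPKM + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneScreenRow",
    "pearson_with_p",
    "gene_summary",
    "screen",
    "stratified_screen",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample matrix of normalized FPKM values.

    Wraps a pandas DataFrame (index = gene symbols, columns = sample ids)
    with validation: identifiers unique, values non-negative and finite.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes[:5]}")
        arr = df.to_numpy(dtype=float)
        if np.isfinite(arr).all() and (arr < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def gene_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read a TSV with gene symbols in the first column, samples across."""
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        return cls(values=df)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass(frozen=True)
class GeneScreenRow:
    """One screen hit: Table-style record of a gene passing every filter."""

    symbol: str
    correlation: float
    p_value: float
    q_value: float
    mean: float
    sd: float
    cv: float

    @property
    def direction(self) -> str:
        return "negative" if self.correlation < 0 else "positive"


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation with its two-sided p-value.

    p is from ``t = r sqrt(n-2) / sqrt(1-r^2)`` on n-2 degrees of freedom
    (equivalently scipy's exact null beta distribution).

    Raises
    ------
    ValueError
        If lengths differ, n < 3, or either vector is constant (correlation
        undefined).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if xa.size < 3:
        raise ValueError(f"need n >= 3 samples, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def gene_summary(values: Sequence[float]) -> Tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator), and coefficient of variation SD/mean.

    Raises
    ------
    ValueError
        If n < 2 or the mean is 0 (all-zero gene: CV undefined).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need n >= 2 values, got {v.size}")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    if m == 0.0:
        raise ValueError("zero-mean gene: CV undefined")
    return m, sd, sd / m


def _bulk_pearson(mat: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised Pearson r and two-sided t-based p of each row of ``mat`` vs ``y``.

    Constant rows yield r = NaN, p = NaN.
    """
    n = y.size
    yc = y - y.mean()
    xc = mat - mat.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum())
    sx = np.sqrt((xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def _align(
    matrix: ExpressionMatrix, sed_by_sample: Mapping[str, float]
) -> Tuple[pd.DataFrame, np.ndarray]:
    common = [s for s in matrix.sample_ids if s in sed_by_sample]
    if len(common) == 0:
        raise ValueError("no overlapping samples between expression matrix and SED values")
    if len(common) < 3:
        raise ValueError(f"need >= 3 overlapping samples, got {len(common)}")
    sub = matrix.values[common]
    sed = np.array([sed_by_sample[s] for s in common], dtype=float)
    return sub, sed


def screen(
    matrix: ExpressionMatrix,
    sed_by_sample: Mapping[str, float],
    p_max: float = 0.01,
    mean_min: float = 10.0,
    cv_min: float = 1.0,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Correlate every gene with SED and keep those passing all filters.

    Returns a DataFrame with columns ``symbol, correlation, p_value, q_value,
    mean, sd, cv`` — negatives sorted ascending by r, then positives
    ascending by r.  q-values (Benjamini-Hochberg over all testable genes)
    are informational only and never filter.

    Genes with any missing value, constant expression, or zero mean are
    dropped with a logged count before testing.
    """
    if matrix.n_genes == 0:
        return _empty_screen_frame()
    sub, sed_vec = _align(matrix, sed_by_sample)
    arr = sub.to_numpy(dtype=float)
    genes = np.asarray(sub.index)

    keep = np.isfinite(arr).all(axis=1)
    n_missing = int((~keep).sum())
    if n_missing:
        logger.info("dropping %d genes with missing values (complete-case per gene)", n_missing)
    arr, genes = arr[keep], genes[keep]

    nonconstant = np.ptp(arr, axis=1) > 0
    nonzero_mean = arr.mean(axis=1) != 0
    testable = nonconstant & nonzero_mean
    n_excluded = int((~testable).sum())
    if n_excluded:
        logger.info("excluding %d constant or all-zero genes", n_excluded)
    arr, genes = arr[testable], genes[testable]
    if arr.shape[0] == 0:
        return _empty_screen_frame()

    test_arr = np.log2(arr + 1.0) if log_transform else arr
    r, p = _bulk_pearson(test_arr, sed_vec)
    means = arr.mean(axis=1)
    sds = arr.std(axis=1, ddof=1)
    cvs = sds / means
    _, q, _, _ = multipletests(p, method="fdr_bh")

    mask = (p < p_max) & (means > mean_min) & (cvs > cv_min)
    out = pd.DataFrame(
        {
            "symbol": genes[mask],
            "correlation": r[mask],
            "p_value": p[mask],
            "q_value": q[mask],
            "mean": means[mask],
            "sd": sds[mask],
            "cv": cvs[mask],
        }
    )
    neg = out[out["correlation"] < 0].sort_values("correlation")
    pos = out[out["correlation"] >= 0].sort_values("correlation")
    return pd.concat([neg, pos], ignore_index=True)


def _empty_screen_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["symbol", "correlation", "p_value", "q_value", "mean", "sd", "cv"]
    )


def stratified_screen(
    matrix: ExpressionMatrix,
    sed_by_sample: Mapping[str, float],
    hr_positive_by_sample: Mapping[str, bool],
    genes: Optional[Iterable[str]] = None,
    min_stratum: int = 3,
) -> pd.DataFrame:
    """Per-gene correlation with SED within hormone-receptor strata.

    For each nominated gene (default: all genes) the Pearson (r, p) is
    computed separately in the HR-positive and HR-negative sample subsets.
    Strata below ``min_stratum`` samples are skipped with a warning.

    Returns a DataFrame with columns ``symbol, stratum, n, correlation,
    p_value``.
    """
    sub, sed_vec = _align(matrix, sed_by_sample)
    samples = np.asarray(sub.columns)
    known = np.array([s in hr_positive_by_sample for s in samples])
    if not known.all():
        logger.info("dropping %d samples without HR status", int((~known).sum()))
    samples, sed_vec = samples[known], sed_vec[known]
    hr = np.array([bool(hr_positive_by_sample[s]) for s in samples])

    gene_list = list(genes) if genes is not None else sub.index.tolist()
    missing = [g for g in gene_list if g not in sub.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")

    rows = []
    for label, mask in (("HR+", hr), ("HR-", ~hr)):
        if mask.sum() < min_stratum:
            warnings.warn(
                f"stratum {label} has {int(mask.sum())} samples (< {min_stratum}); skipped",
                stacklevel=2,
            )
            continue
        svals = sed_vec[mask]
        for gsym in gene_list:
            expr = sub.loc[gsym, samples[mask]].to_numpy(dtype=float)
            if np.ptp(expr) == 0 or np.ptp(svals) == 0:
                rows.append((gsym, label, int(mask.sum()), np.nan, np.nan))
                continue
            r, p = pearson_with_p(expr, svals)
            rows.append((gsym, label, int(mask.sum()), r, p))
    return pd.DataFrame(rows, columns=["symbol", "stratum", "n", "correlation", "p_value"])
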
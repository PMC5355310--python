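"""Filtration, imputation, and normalization of beta / expression matrices.

Stage order is fixed: missingness filter -> kNN imputation -> quantile
normalization (-> log2(x+1) for expression). The filter bounds per-row
missingness so imputation is well posed; normalization requires a complete
matrix. Each cohort is processed independently; matrices are never pooled
across cohorts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .containers import EmptyResultError

logger = logging.getLogger(__name__)


def filter_missing(
    matrix: pd.DataFrame, max_missing_fraction: float = 0.05
) -> tuple[pd.DataFrame, list]:
    """Drop rows whose missing fraction strictly exceeds the threshold.

    The cutoff is exclusive: a row at exactly ``max_missing_fraction`` is
    retained ("over 5%" means > 0.05). Row order is preserved.

    Returns
    -------
    (filtered, dropped_ids)

    Raises
    ------
    EmptyResultError
        If every row is dropped.
    """
    if matrix.shape[0] == 0:
        raise ValueError("matrix has no rows")
    frac = matrix.isna().mean(axis=1)
    keep = frac <= max_missing_fraction
    dropped = list(matrix.index[~keep])
    if not keep.any():
        raise EmptyResultError(
            f"all {matrix.shape[0]} rows exceed missing fraction {max_missing_fraction}"
        )
    if dropped:
        logger.info("filter_missing: dropped %d/%d rows", len(dropped), matrix.shape[0])
    return matrix.loc[keep], dropped


def impute_knn(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Fill missing entries from the k nearest rows.

    For a missing entry (row r, column c) the eligible neighbors are the
    other rows with an observed value in column c and a finite nan-Euclidean
    distance to row r (distance over co-observed columns, rescaled for the
    number observed). With at least k eligible neighbors the entry becomes the
    mean of the k nearest neighbors' values in column c (distance ties broken
    by row order); with fewer than k, the row's own observed mean is used.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if not matrix.isna().to_numpy().any():
        return matrix
    X = matrix.to_numpy(dtype=float)
    out = X.copy()
    dist = nan_euclidean_distances(X)
    np.fill_diagonal(dist, np.nan)
    observed = ~np.isnan(X)
    row_means = np.nanmean(np.where(observed, X, np.nan), axis=1)
    miss_rows, miss_cols = np.nonzero(~observed)
    for r, c in zip(miss_rows, miss_cols):
        d = dist[r].copy()
        d[~observed[:, c]] = np.nan
        eligible = np.nonzero(~np.isnan(d))[0]
        if len(eligible) < k:
            out[r, c] = row_means[r]
            continue
        order = eligible[np.lexsort((eligible, d[eligible]))][:k]
        out[r, c] = X[order, c].mean()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns (samples).

    Every column is forced onto one reference distribution: the element-wise
    mean of the sorted columns. Ranks are assigned per column; entries tied
    within a column receive the mean of the reference values at their tied
    ranks. Afterwards all columns share a single multiset of values. A
    single-column matrix is returned unchanged (the reference is the column
    itself).
    """
    if matrix.isna().to_numpy().any():
        raise ValueError("quantile_normalize requires a complete matrix (impute first)")
    if matrix.shape[1] <= 1:
        return matrix.copy()
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        pos = np.empty(n, dtype=int)
        pos[order] = np.arange(n)
        assigned = reference[pos]
        # average the reference values across entries tied within the column
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=assigned)
        out[:, j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log_transform_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply log2(x + 1) entry-wise to a complete, non-negative matrix."""
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        r, c = np.argwhere(np.isnan(X))[0]
        raise ValueError(f"missing entry at ({matrix.index[r]}, {matrix.columns[c]})")
    if (X < 0).any():
        r, c = np.argwhere(X < 0)[0]
        raise ValueError(
            f"negative entry {X[r, c]} at ({matrix.index[r]}, {matrix.columns[c]})"
        )
    return pd.DataFrame(np.log2(X + 1.0), index=matrix.index, columns=matrix.columns)


def preprocess_beta(
    matrix: pd.DataFrame,
    max_missing_fraction: float = 0.05,
    k: int = 10,
    normalize: bool = True,
) -> tuple[pd.DataFrame, list]:
    """filter -> impute -> quantile normalize, clipping betas back to [0, 1].

    Normalization can push a value outside [0, 1] only by floating rounding;
    the clip restores the beta-value invariant.
    """
    filtered, dropped = filter_missing(matrix, max_missing_fraction)
    complete = impute_knn(filtered, k)
    if normalize:
        complete = quantile_normalize(complete).clip(lower=0.0, upper=1.0)
    return complete, dropped


def preprocess_expression(
    matrix: pd.DataFrame,
    max_missing_fraction: float = 0.05,
    k: int = 10,
    normalize: bool = True,
    log_transform: bool = True,
) -> tuple[pd.DataFrame, list]:
    """filter -> impute -> quantile normalize -> log2(x+1)."""
    filtered, dropped = filter_missing(matrix, max_missing_fraction)
    complete = impute_knn(filtered, k)
    if normalize:
        complete = quantile_normalize(complete)
    if log_transform:
        complete = log_transform_expression(complete.clip(lower=0.0))
    return complete, dropped
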
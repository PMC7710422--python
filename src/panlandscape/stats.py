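"""Shared statistical primitives: BH adjustment and Spearman correlation.

Every landscape stage controls the false discovery rate with the
Benjamini-Hochberg step-up procedure, applied within a cancer type across
the genes (or gene x pathway / gene x drug cells) tested there. Spearman
correlations use average ranks for ties and the t-distribution
approximation for the p-value; batch (matrix x matrix) correlation has a
vectorized rank-then-Pearson fast path used when no values are missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["benjamini_hochberg", "spearman", "spearman_matrix"]


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    NaN entries pass through as NaN and do not count toward the number of
    tests. Raises if any finite entry falls outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        bad = p[finite][(p[finite] < 0) | (p[finite] > 1)][0]
        raise ValueError(f"p-value {bad} outside [0, 1]")
    out = np.full_like(p, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def _spearman_p_from_rho(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p via the t-approximation, t = rho * sqrt((n-2)/(1-rho^2))."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(np.abs(t), np.maximum(n - 2, 1))
    # |rho| == 1 gives infinite t: p -> 0
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return np.where(np.isnan(rho), np.nan, p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho and p for one pair, pairwise-complete on missing values.

    Returns ``(nan, nan)`` for < 3 complete pairs or a constant input
    (undefined rank correlation) instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return rho, float(_spearman_p_from_rho(rho, len(x)))


def spearman_matrix(
    left: pd.DataFrame, right: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman between rows of ``left`` and rows of ``right``.

    Both frames must share the same columns (samples), already aligned.
    Returns ``(rho, p, n)`` frames indexed by (left row, right row). When
    neither frame has missing values the whole grid is computed with one
    rank + matrix product; otherwise pairs with missing data fall back to
    the pairwise-complete scalar path.
    """
    if list(left.columns) != list(right.columns):
        raise ValueError("left and right must share an identical sample order")
    nL, nR = len(left), len(right)
    n_samples = left.shape[1]
    rho = np.full((nL, nR), np.nan)
    nobs = np.full((nL, nR), 0.0)

    left_arr = left.to_numpy(dtype=float)
    right_arr = right.to_numpy(dtype=float)
    left_nan = np.isnan(left_arr).any(axis=1)
    right_nan = np.isnan(right_arr).any(axis=1)

    clean_L = np.where(~left_nan)[0]
    clean_R = np.where(~right_nan)[0]
    if clean_L.size and clean_R.size and n_samples >= 3:
        rl = np.apply_along_axis(sps.rankdata, 1, left_arr[clean_L])
        rr = np.apply_along_axis(sps.rankdata, 1, right_arr[clean_R])
        rl = rl - rl.mean(axis=1, keepdims=True)
        rr = rr - rr.mean(axis=1, keepdims=True)
        sl = np.sqrt((rl**2).sum(axis=1))
        sr = np.sqrt((rr**2).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            block = (rl @ rr.T) / np.outer(sl, sr)
        rho[np.ix_(clean_L, clean_R)] = block
        nobs[np.ix_(clean_L, clean_R)] = n_samples

    # pairwise-complete fallback for any row pair touched by missing data
    dirty_pairs = [
        (i, j)
        for i in range(nL)
        for j in range(nR)
        if left_nan[i] or right_nan[j]
    ]
    for i, j in dirty_pairs:
        x, y = left_arr[i], right_arr[j]
        ok = ~(np.isnan(x) | np.isnan(y))
        r, _ = spearman(x, y)
        rho[i, j] = r
        nobs[i, j] = ok.sum()

    p = _spearman_p_from_rho(rho, nobs)
    idxL, idxR = left.index, right.index
    return (
        pd.DataFrame(rho, index=idxL, columns=idxR),
        pd.DataFrame(p, index=idxL, columns=idxR),
        pd.DataFrame(nobs, index=idxL, columns=idxR),
    )
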
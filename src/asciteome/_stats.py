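"""Shared statistical helpers (vectorized Spearman, BH adjustment)."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def rowwise_spearman(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p per row of two equal-shape (G, n) arrays.

    Ranks use midranks for ties (matching ``scipy.stats.spearmanr``); the
    p-value uses the same t-approximation scipy applies for n > 2. Rows
    where either variable is constant yield NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    n = x.shape[1]
    rx = stats.rankdata(x, axis=1)
    ry = stats.rankdata(y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    sx = np.sqrt((rx**2).sum(axis=1))
    sy = np.sqrt((ry**2).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry).sum(axis=1) / denom
    rho = np.where(denom == 0, np.nan, np.clip(rho, -1.0, 1.0))
    # t approximation, two-sided
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(
        np.isnan(rho),
        np.nan,
        np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2)),
    )
    return rho, p


def spearman_vs_vector(x: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman of each row of ``x`` (G, n) against one score vector (n,)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    s = np.broadcast_to(np.asarray(score, dtype=float), x.shape)
    return rowwise_spearman(x, s)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def significance_stars(p: float) -> str:
    """Star annotation at the conventional p < 0.05/0.01/0.001/0.0001 levels."""
    if np.isnan(p):
        return ""
    for thr, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thr:
            return stars
    return ""
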
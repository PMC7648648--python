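"""Vectorized statistical primitives shared across modules."""

from __future__ import annotations

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

EXPM1_PSEUDOCOUNT = 1e-9


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    out = np.ones_like(p)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per column of x vs y.

    Uses the tie-corrected normal approximation; columns that are
    constant across both groups get p = 1.
    """
    res = scipy.stats.mannwhitneyu(
        x, y, axis=0, alternative="two-sided", method="asymptotic"
    )
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    # constant columns: identical values in both groups carry no signal
    both = np.vstack([x, y])
    constant = both.max(axis=0) == both.min(axis=0)
    p[constant] = 1.0
    return np.clip(p, 0.0, 1.0)


def log2_fold_change(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """log2 fold-change of group means on the expm1 (de-logged) scale.

    Columns that are all-zero in both groups get 0 by convention.
    """
    mx = np.expm1(x).mean(axis=0)
    my = np.expm1(y).mean(axis=0)
    lfc = np.log2((mx + EXPM1_PSEUDOCOUNT) / (my + EXPM1_PSEUDOCOUNT))
    lfc[(mx == 0) & (my == 0)] = 0.0
    return lfc


def spearman_vs_vector(x: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p of each column of x against vector v.

    The p-value uses the t approximation with n - 2 degrees of freedom.
    Constant columns get rho = 0, p = 1 by convention.
    """
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations for a correlation")
    rx = scipy.stats.rankdata(x, axis=0)
    rv = scipy.stats.rankdata(v)
    rx = rx - rx.mean(axis=0)
    rv = rv - rv.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (rv**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * rv[:, None]).sum(axis=0) / denom
    constant = denom == 0
    rho[constant] = 0.0
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.abs(rho) == 1.0] = 0.0
    p[constant] = 1.0
    return rho, np.clip(p, 0.0, 1.0)


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Classical equal-variance two-sample Student's t.

    Returns (t, df, two-sided p).  Degenerate zero-variance input follows
    the conventions: equal means -> (0, df, 1); unequal means -> p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 values for a t-test")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        import warnings

        warnings.warn("zero pooled variance with unequal means; p = 0")
        return float(np.sign(diff) * np.inf), df, 0.0
    t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=df)
    return float(t), df, float(p)
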
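"""Thin statistical layer over per-cycle swallow summaries.

One-sample and paired Wilcoxon signed-rank tests (exact distribution for
n <= 25 without ties, normal approximation with continuity correction above),
Bonferroni adjustment of the significance threshold across comparisons, and
pairwise-complete Pearson correlation matrices with two-sided t-based
p-values.  Cycles are pooled across animals (treated as independent), matching
the original analysis; zero differences are dropped from the signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "signed_rank_tests",
    "correlation_matrix",
]

ALPHA = 0.05


def _wilcoxon(x: np.ndarray, y: np.ndarray | None = None) -> tuple[float, float, int]:
    """Signed-rank statistic, two-sided p, and effective n (zeros dropped)."""
    d = np.asarray(x, float) if y is None else np.asarray(x, float) - np.asarray(y, float)
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return np.nan, np.nan, 0
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, method=method, correction=(method == "approx"))
    return float(res.statistic), float(res.pvalue), n


def signed_rank_tests(
    table: pd.DataFrame,
    comparisons: list[tuple],
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Wilcoxon signed-rank tests with a Bonferroni-adjusted threshold.

    ``comparisons`` entries are (name, column) for one-sample tests against
    zero or (name, column_a, column_b) for paired tests.  Requires at least 6
    non-missing (non-zero-difference) pairs per comparison; comparisons below
    that, or with all-zero differences, are reported as undefined (NaN p).
    The per-test threshold is alpha / m for m comparisons.
    """
    m = len(comparisons)
    threshold = alpha / m if m else alpha
    rows = []
    for comp in comparisons:
        if len(comp) == 2:
            name, col = comp
            stat, p, n = _wilcoxon(table[col].to_numpy())
        else:
            name, col_a, col_b = comp
            stat, p, n = _wilcoxon(table[col_a].to_numpy(), table[col_b].to_numpy())
        if n < 6:
            stat, p = np.nan, np.nan
        rows.append(
            {
                "comparison": name,
                "n": n,
                "statistic": stat,
                "p": p,
                "p_threshold": threshold,
                "significant": bool(p < threshold) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r and two-sided p matrices.

    Pairs with fewer than 3 complete observations or zero variance yield NaN.
    """
    cols = columns or list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x = table[cols[i]].to_numpy(float)
            y = table[cols[j]].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                continue
            xs, ys = x[ok], y[ok]
            if np.std(xs) == 0 or np.std(ys) == 0:
                continue
            res = sps.pearsonr(xs, ys)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )
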
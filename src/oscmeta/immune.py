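"""Immune-cell fraction comparison between marker-high and -low samples.

Deconvolved fractions (e.g. CIBERSORT's 22-cell-type panel) are an input;
this module splits samples at the median of the marker's expression and
compares each cell type's proportions between groups with a two-sided
t-test (Welch by default, pooled-variance behind a flag).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

EXPRESSION_COL = "expression"


def validate_fractions(table: pd.DataFrame, tol: float = 1e-6) -> None:
    """Rows must be simplex vectors: entries in [0,1], summing to 1."""
    frac = table.drop(columns=[EXPRESSION_COL], errors="ignore")
    vals = frac.to_numpy(dtype=float)
    if np.any(vals < -tol) or np.any(vals > 1 + tol):
        raise ValueError("fractions must lie in [0, 1]")
    sums = vals.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > tol):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"row {bad} fractions sum to {sums[bad]:.6f}, not 1")


def split_by_median_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Assign 'high'/'low' groups at the median expression (ties -> low)."""
    if len(table) < 4:
        raise ValueError("need at least 4 samples to split")
    expr = table[EXPRESSION_COL].to_numpy(dtype=float)
    if np.all(expr == expr[0]):
        raise ValueError("constant expression; no median split exists")
    med = np.median(expr)
    out = table.copy()
    out["group"] = np.where(expr > med, "high", "low")
    return out


def per_celltype_test(
    grouped: pd.DataFrame, *, equal_var: bool = False, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-cell-type two-sided t-test of fractions, high vs low group.

    Output schema (one row per cell type, sorted by p): n, mean, SD per
    group, t, p, significance flag, and a supplementary BH-adjusted p.
    The t statistic is oriented low-minus-high so a negative value means
    higher infiltration in the marker-high group.  Cell types constant in
    both groups get p = 1.
    """
    cells = [c for c in grouped.columns if c not in (EXPRESSION_COL, "group")]
    lo = grouped[grouped["group"] == "low"]
    hi = grouped[grouped["group"] == "high"]
    if len(lo) < 2 or len(hi) < 2:
        raise ValueError("both groups need at least 2 samples")
    rows = []
    for cell in cells:
        a = lo[cell].to_numpy(dtype=float)
        b = hi[cell].to_numpy(dtype=float)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "cell_type": cell,
                "n_low": len(a),
                "mean_low": a.mean(),
                "sd_low": a.std(ddof=1),
                "n_high": len(b),
                "mean_high": b.mean(),
                "sd_high": b.std(ddof=1),
                "t": float(t),
                "p": float(p),
            }
        )
    df = pd.DataFrame(rows)
    from .coexpression import bh_adjust

    df["adj_p"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p"] < alpha
    return df.sort_values("p", kind="stable").reset_index(drop=True)
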
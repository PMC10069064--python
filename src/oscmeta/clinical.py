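"""In-house assay statistics: qPCR fold change, adaptive paired/group
tests, IHC dichotomization, positivity rates and chi-square association.

These mirror how a clinical cohort is summarized: relative qPCR
quantification by 2^-ddCt against a housekeeping gene, staining scores
collapsed to a binary positivity call, and Pearson chi-square (no
continuity correction) linking positivity to clinico-pathological strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("oscmeta")


@dataclass(frozen=True)
class QpcrRecord:
    """Cycle thresholds for target and reference gene, case and control."""

    sample_id: str
    ct_target_case: float
    ct_ref_case: float
    ct_target_ctrl: float
    ct_ref_ctrl: float


def fold_change_ddct(rec: QpcrRecord) -> float:
    """Relative quantification 2^-ddCt.

    dCt_case = Ct(target,case) - Ct(ref,case); dCt_ctrl analogous;
    ddCt = dCt_case - dCt_ctrl; fold change = 2^-ddCt.
    """
    cts = (rec.ct_target_case, rec.ct_ref_case, rec.ct_target_ctrl, rec.ct_ref_ctrl)
    if any(c is None or not np.isfinite(c) or c <= 0 for c in cts):
        raise ValueError(f"{rec.sample_id}: invalid cycle threshold values")
    dct_case = rec.ct_target_case - rec.ct_ref_case
    dct_ctrl = rec.ct_target_ctrl - rec.ct_ref_ctrl
    return float(2.0 ** (-(dct_case - dct_ctrl)))


def paired_compare(
    case_values: Sequence[float], control_values: Sequence[float], alpha: float = 0.05
) -> tuple[str, float, float]:
    """Paired comparison with variance-homogeneity-driven test selection.

    Levene's test (median-centered) at ``alpha`` decides: homogeneous
    variances -> paired t-test, otherwise Wilcoxon signed-rank.  Returns
    (test name, statistic, two-sided p).  All-zero differences are
    degenerate and reported as p = 1; zero-variance nonzero differences
    drive the paired t to infinity, reported as p = 0.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    if np.all(diff == 0):
        logger.info("paired_compare: all differences zero -> degenerate, p=1")
        return "degenerate", 0.0, 1.0
    _, lev_p = stats.levene(x, y, center="median")
    if np.isnan(lev_p) or lev_p >= alpha:
        # constant nonzero shift (up to fp noise): t -> infinity
        if diff.std(ddof=1) <= 1e-12 * abs(diff.mean()):
            logger.info("paired_compare: zero-variance nonzero differences -> p=0")
            return "paired-t", float(np.inf) * np.sign(diff.mean()), 0.0
        stat, p = stats.ttest_rel(x, y)
        name = "paired-t"
    else:
        stat, p = stats.wilcoxon(x, y)
        name = "wilcoxon"
    logger.info("paired_compare: levene p=%.4g -> %s", lev_p, name)
    return name, float(stat), float(p)


def group_compare_auto(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> tuple[str, float, float]:
    """Normality-driven selection between parametric and rank tests.

    Shapiro–Wilk per group at ``alpha``: all normal -> Student t (2 groups)
    or one-way ANOVA (>2); any non-normal or zero-variance group -> the
    Mann–Whitney or Kruskal–Wallis branch.  All tests two-sided.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 3 for a in arrs):
        raise ValueError("each group needs at least 3 values")
    normal = True
    for a in arrs:
        if a.std(ddof=1) == 0:
            normal = False
            logger.info("group_compare_auto: zero-variance group -> nonparametric branch")
            break
        if stats.shapiro(a).pvalue < alpha:
            normal = False
            break
    if normal:
        if len(arrs) == 2:
            stat, p = stats.ttest_ind(arrs[0], arrs[1])
            name = "student-t"
        else:
            stat, p = stats.f_oneway(*arrs)
            name = "anova"
    else:
        if len(arrs) == 2:
            stat, p = stats.mannwhitneyu(arrs[0], arrs[1], alternative="two-sided")
            name = "mann-whitney"
        else:
            stat, p = stats.kruskal(*arrs)
            name = "kruskal-wallis"
    logger.info("group_compare_auto: %s", name)
    return name, float(stat), float(p)


def ihc_dichotomize(scores: Sequence[int]) -> np.ndarray:
    """Collapse 0-3 staining intensities to binary positivity.

    No (0) or weak (1) staining is negative; moderate (2) or strong (3)
    staining is positive.
    """
    s = np.asarray(scores)
    if not np.isin(s, [0, 1, 2, 3]).all():
        bad = s[~np.isin(s, [0, 1, 2, 3])][0]
        raise ValueError(f"IHC score out of range: {bad!r}")
    return (s >= 2).astype(int)


def positivity_rate(
    table: pd.DataFrame,
    stratum: dict[str, object] | None = None,
    positive_col: str = "positive",
) -> tuple[float, int, int]:
    """Percent positive within an optional stratum filter.

    Returns (rate %, numerator, denominator) with the rate rounded half-up
    to 2 decimals.
    """
    sub = table
    if stratum:
        for col, val in stratum.items():
            sub = sub[sub[col] == val]
    den = len(sub)
    if den == 0:
        raise ValueError(f"empty stratum: {stratum}")
    num = int(sub[positive_col].sum())
    rate = float(Decimal(100 * num / den).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return rate, num, den


def chi2_association(
    counts: Sequence[Sequence[int]], *, correction: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction by default — the convention that reproduces
    printed 2x2 clinical association tables.  Returns (chi2, df, p).
    """
    obs = np.asarray(counts)
    if np.any(obs < 0) or not np.issubdtype(obs.dtype, np.number):
        raise ValueError("counts must be non-negative numbers")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    if obs.sum() == 0:
        raise ValueError("empty contingency table")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return float(chi2), int(df), float(p)


def clinical_association_table(
    table: pd.DataFrame,
    strata_cols: Sequence[str],
    positive_col: str = "positive",
) -> pd.DataFrame:
    """Per-stratum positivity counts, rates, and chi-square p per variable.

    For each clinical variable the full r x 2 table is tested; variables
    with more than two levels additionally get all pairwise 2x2 p-values
    (unadjusted, as clinical tables conventionally print them).
    """
    rows = []
    for col in strata_cols:
        levels = sorted(table[col].dropna().unique(), key=str)
        counts = []
        for lev in levels:
            sub = table[table[col] == lev]
            pos = int(sub[positive_col].sum())
            counts.append([pos, len(sub) - pos])
        _, _, p_overall = chi2_association(counts)
        for lev, (pos, neg) in zip(levels, counts):
            rate, num, den = positivity_rate(table, {col: lev}, positive_col)
            rows.append(
                {
                    "variable": col,
                    "level": str(lev),
                    "positive": pos,
                    "negative": neg,
                    "rate_pct": rate,
                    "p_overall": p_overall,
                }
            )
        if len(levels) > 2:
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    _, _, p = chi2_association([counts[i], counts[j]])
                    rows.append(
                        {
                            "variable": col,
                            "level": f"{levels[i]} vs {levels[j]}",
                            "positive": np.nan,
                            "negative": np.nan,
                            "rate_pct": np.nan,
                            "p_overall": p,
                        }
                    )
    return pd.DataFrame(rows)
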
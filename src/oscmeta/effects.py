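"""Standardized-mean-difference meta-analysis across expression cohorts.

Each cohort contributes a Hedges g (small-sample-corrected Cohen d) for a
gene's tumor-vs-normal contrast.  Cohort effects are pooled with the
DerSimonian–Laird random-effects estimator; genes are then called up- or
down-regulated purely from the sign of the pooled 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

Z95 = 1.959963984540054  # normal 97.5% quantile used for all forest CIs


@dataclass(frozen=True)
class EffectSizeRecord:
    """One cohort's standardized mean difference for one gene."""

    dataset_id: str
    g: float
    var_g: float
    ci_low: float
    ci_high: float
    n_tumor: int
    n_normal: int


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects (DerSimonian–Laird) pooled SMD with heterogeneity."""

    pooled_g: float
    se: float
    ci_low: float
    ci_high: float
    Q: float
    tau2: float
    I2: float
    k: int


def hedges_g(
    tumor_values: Sequence[float],
    normal_values: Sequence[float],
    dataset_id: str = "",
    *,
    correct: bool = True,
) -> EffectSizeRecord:
    """Hedges g for a tumor-vs-normal contrast.

    d = (mean_T - mean_N) / s_pooled with the df-weighted pooled SD;
    J = 1 - 3/(4(n_T+n_N-2)-1) is the small-sample correction (g = J*d,
    ``correct=False`` gives plain Cohen d);
    var_g = (n_T+n_N)/(n_T*n_N) + g^2/(2(n_T+n_N)).

    Raises ``ValueError`` on groups smaller than 2 or zero pooled SD.
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(normal_values, dtype=float)
    if t.size < 2 or n.size < 2:
        raise ValueError("each group needs at least 2 values")
    nt, nn = t.size, n.size
    df = nt + nn - 2
    s_pooled = np.sqrt(((nt - 1) * t.var(ddof=1) + (nn - 1) * n.var(ddof=1)) / df)
    if s_pooled <= 0 or not np.isfinite(s_pooled):
        raise ValueError("zero pooled standard deviation (degenerate input)")
    d = (t.mean() - n.mean()) / s_pooled
    J = 1.0 - 3.0 / (4.0 * df - 1.0) if correct else 1.0
    g = J * d
    var_g = (nt + nn) / (nt * nn) + g * g / (2.0 * (nt + nn))
    half = Z95 * np.sqrt(var_g)
    return EffectSizeRecord(dataset_id, g, var_g, g - half, g + half, nt, nn)


def hedges_g_matrix(
    tumor: np.ndarray, normal: np.ndarray, *, correct: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Hedges g over genes (rows) for one cohort.

    Returns ``(g, var_g)`` arrays; genes whose pooled SD is zero get NaN.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    nt, nn = tumor.shape[1], normal.shape[1]
    df = nt + nn - 2
    sp2 = ((nt - 1) * tumor.var(axis=1, ddof=1) + (nn - 1) * normal.var(axis=1, ddof=1)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (tumor.mean(axis=1) - normal.mean(axis=1)) / np.sqrt(sp2)
    d[sp2 <= 0] = np.nan
    J = 1.0 - 3.0 / (4.0 * df - 1.0) if correct else 1.0
    g = J * d
    var_g = (nt + nn) / (nt * nn) + g * g / (2.0 * (nt + nn))
    return g, var_g


def pool_dl(records: Sequence[EffectSizeRecord], *, model: str = "dl") -> PooledEffect:
    """DerSimonian–Laird random-effects pooling of per-cohort effects.

    Fixed-effect weights w_i = 1/var_i define Q; the method-of-moments
    tau^2 = max(0, (Q-(k-1)) / (Sw - Sw2/Sw)) feeds random-effects weights
    1/(var_i + tau^2).  ``model='fixed'`` forces tau^2 = 0.
    """
    if len(records) == 0:
        raise ValueError("cannot pool an empty set of effect sizes")
    g = np.array([r.g for r in records], dtype=float)
    v = np.array([r.var_g for r in records], dtype=float)
    k = g.size
    w = 1.0 / v
    g_fixed = float((w * g).sum() / w.sum())
    Q = float((w * (g - g_fixed) ** 2).sum())
    if k > 1 and model == "dl":
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    else:
        tau2 = 0.0
    ws = 1.0 / (v + tau2)
    pooled = float((ws * g).sum() / ws.sum())
    se = float(1.0 / np.sqrt(ws.sum()))
    I2 = max(0.0, (Q - (k - 1)) / Q) if Q > 0 else 0.0
    return PooledEffect(pooled, se, pooled - Z95 * se, pooled + Z95 * se, Q, tau2, I2, k)


def pool_genes(
    per_gene_records: Mapping[str, Sequence[EffectSizeRecord]], *, model: str = "dl"
) -> dict[str, PooledEffect]:
    """Pool every gene's cohort effects; genes with no usable record are skipped."""
    out: dict[str, PooledEffect] = {}
    for gene, recs in per_gene_records.items():
        recs = [r for r in recs if np.isfinite(r.g) and np.isfinite(r.var_g)]
        if recs:
            out[gene] = pool_dl(recs, model=model)
    return out


def call_degs_by_smd(
    per_gene_pooled: Mapping[str, PooledEffect],
) -> tuple[set[str], set[str]]:
    """CI-sign differential-expression caller.

    up   = genes whose pooled 95% CI lower limit is > 0,
    down = genes whose pooled 95% CI upper limit is < 0;
    everything else is left uncalled.  The two sets are disjoint by
    construction.
    """
    up = {g for g, p in per_gene_pooled.items() if p.ci_low > 0}
    down = {g for g, p in per_gene_pooled.items() if p.ci_high < 0}
    return up, down


def forest_table(
    records: Sequence[EffectSizeRecord], pooled: PooledEffect
) -> pd.DataFrame:
    """Forest-plot table: one row per cohort plus a pooled summary row.

    Weight %% are the random-effects weights 1/(var_i + tau^2) normalized
    to 100.
    """
    v = np.array([r.var_g for r in records], dtype=float)
    ws = 1.0 / (v + pooled.tau2)
    weights = 100.0 * ws / ws.sum()
    rows = [
        {
            "dataset_id": r.dataset_id,
            "g": r.g,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "weight_pct": weights[i],
            "n_tumor": r.n_tumor,
            "n_normal": r.n_normal,
        }
        for i, r in enumerate(records)
    ]
    rows.append(
        {
            "dataset_id": "POOLED",
            "g": pooled.pooled_g,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "weight_pct": 100.0,
            "n_tumor": int(sum(r.n_tumor for r in records)),
            "n_normal": int(sum(r.n_normal for r in records)),
        }
    )
    return pd.DataFrame(rows)
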
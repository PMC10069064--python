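"""Co-expression screening and gene-set over-representation.

A gene is co-expressed with the target when it is (a) a final DEG by the
pooled-SMD CI-sign rule and (b) significantly correlated with the target
(BH-adjusted p < alpha, consistent sign) in at least a vote-count threshold
of independent cohorts (defaults: >=7 for positive, >=5 for negative).
Selected genes feed a hypergeometric over-representation test against GMT
gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ingest import ExpressionDataset, GeneSetCollection


@dataclass(frozen=True)
class CorrelationRecord:
    gene: str
    dataset_id: str
    r: float
    p: float
    adj_p: float


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # selected size
    N: int  # universe size
    p: float
    adj_p: float
    genes: tuple[str, ...]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prelim_de_screen(
    ds: ExpressionDataset, lfc_min: float = 1.0, alpha: float = 0.05
) -> tuple[set[str], set[str]]:
    """Per-cohort Welch-t differential-expression screen.

    log2FC is the tumor-minus-normal mean difference on the log scale; a
    gene passes when BH-adjusted p < alpha and \\|log2FC\\| >= lfc_min.
    Constant genes get p = 1.
    """
    tum = ds.matrix[:, ds.group == "tumor"]
    nor = ds.matrix[:, ds.group == "normal"]
    if tum.shape[1] < 3 or nor.shape[1] < 3:
        raise ValueError("both groups need at least 3 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.ttest_ind(tum, nor, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    lfc = tum.mean(axis=1) - nor.mean(axis=1)
    adj = bh_adjust(p)
    sel = (adj < alpha) & (np.abs(lfc) >= lfc_min)
    up = {g for g, s, f in zip(ds.gene_ids, sel, lfc) if s and f > 0}
    down = {g for g, s, f in zip(ds.gene_ids, sel, lfc) if s and f < 0}
    return up, down


def correlate_target(
    ds: ExpressionDataset, target_gene: str, method: str = "pearson"
) -> list[CorrelationRecord]:
    """Correlate every gene with the target across all samples of a cohort.

    Pearson p-values use the exact t transform; Spearman the large-sample
    approximation.  Zero-variance genes are skipped.  BH adjustment is
    applied across the genes actually tested.
    """
    if target_gene not in ds.gene_index:
        raise KeyError(f"target gene {target_gene!r} not in dataset {ds.dataset_id}")
    n = ds.matrix.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples for correlation")
    x = ds.matrix[ds.gene_index[target_gene]]
    if method == "spearman":
        x_r = stats.rankdata(x)
        mat = np.apply_along_axis(stats.rankdata, 1, ds.matrix)
    else:
        x_r, mat = x, ds.matrix
    xc = x_r - x_r.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sm = np.sqrt((mc**2).sum(axis=1))
    valid = (sm > 0) & (sx > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (mc @ xc) / (sm * sx)
    r = np.clip(r, -1.0, 1.0)
    tiny = np.finfo(float).tiny
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r**2, tiny))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.maximum(p, tiny)  # perfect correlation: smallest positive
    genes = [g for g, v in zip(ds.gene_ids, valid) if v]
    pv = p[valid]
    rv = r[valid]
    adj = bh_adjust(pv)
    return [
        CorrelationRecord(g, ds.dataset_id, float(ri), float(pi), float(ai))
        for g, ri, pi, ai in zip(genes, rv, pv, adj)
    ]


def vote_count_coexpression(
    correlations_by_dataset: Mapping[str, Sequence[CorrelationRecord]],
    degs_up: set[str],
    degs_down: set[str],
    up_min_datasets: int = 7,
    down_min_datasets: int = 5,
    alpha: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Vote-counted co-expression selection across cohorts.

    Positive: significant positive correlation in >= up_min_datasets cohorts
    AND in the SMD-up DEG set.  Negative: significant negative correlation
    in >= down_min_datasets cohorts AND in the SMD-down set.
    """
    n_ds = len(correlations_by_dataset)
    if up_min_datasets > n_ds and down_min_datasets > n_ds:
        import warnings

        warnings.warn("vote-count thresholds exceed the number of datasets; empty result")
        return set(), set()
    pos_votes: dict[str, int] = {}
    neg_votes: dict[str, int] = {}
    for recs in correlations_by_dataset.values():
        for rec in recs:
            if rec.adj_p < alpha:
                if rec.r > 0:
                    pos_votes[rec.gene] = pos_votes.get(rec.gene, 0) + 1
                elif rec.r < 0:
                    neg_votes[rec.gene] = neg_votes.get(rec.gene, 0) + 1
    pos = {g for g, v in pos_votes.items() if v >= up_min_datasets} & degs_up
    neg = {g for g, v in neg_votes.items() if v >= down_min_datasets} & degs_down
    return pos, neg


def hypergeom_enrich(
    selected: Iterable[str],
    gene_sets: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    p = P(X >= k) for X ~ Hypergeom(N, K, n) with N the universe size, K
    the set size within the universe, n the selected size, k the overlap.
    BH adjustment across sets; results sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & universe
    n = len(selected)
    N = len(universe)
    rows = []
    for set_id, (desc, members) in gene_sets.sets.items():
        K_genes = set(members) & universe
        K = len(K_genes)
        if K == 0:
            continue
        overlap = tuple(sorted(selected & K_genes))
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, k, K, overlap, min(p, 1.0)))
    if not rows:
        return []
    adj = bh_adjust([r[4] for r in rows])
    out = [
        EnrichmentResult(set_id, k, K, n, N, p, float(a), overlap)
        for (set_id, k, K, overlap, p), a in zip(rows, adj)
    ]
    out.sort(key=lambda e: (e.p, e.set_id))
    return out


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_id": e.set_id,
                "overlap": e.k,
                "set_size": e.K,
                "selected": e.n,
                "universe": e.N,
                "p": e.p,
                "adj_p": e.adj_p,
                "genes": ",".join(e.genes),
            }
            for e in results
        ]
    )
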
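"""Reading, validation, scaling and merging of expression cohorts.

The pipeline works on the log2(x + 0.001) scale throughout: raw TPM or
microarray intensities are transformed on ingest (with an automatic
large-value heuristic), samples within a cohort are quantile-normalized,
and cohorts sharing a platform are concatenated after gene-wise per-batch
mean centering.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("oscmeta")

LOG_PSEUDOCOUNT = 0.001
AUTO_LOG_PERCENTILE = 99.0
AUTO_LOG_THRESHOLD = 50.0


@dataclass(frozen=True)
class ExpressionDataset:
    """One cohort: gene x sample matrix plus tumor/normal labels.

    ``scale`` records whether values are raw (TPM/intensity) or already
    log-like; ``batch`` optionally tracks each sample's source dataset
    after a platform merge.
    """

    dataset_id: str
    platform_id: str
    matrix: np.ndarray
    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    group: np.ndarray  # per-sample 'tumor' / 'normal'
    scale: str = "log"
    batch: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        ng, ns = self.matrix.shape
        if ng != len(self.gene_ids) or ns != len(self.sample_ids):
            raise ValueError("matrix dimensions do not match identifier lists")
        if len(set(self.gene_ids)) != ng:
            raise ValueError(f"duplicate gene identifiers in {self.dataset_id}")
        if len(set(self.sample_ids)) != ns:
            raise ValueError(f"duplicate sample identifiers in {self.dataset_id}")
        if len(self.group) != ns:
            raise ValueError("group labels must cover every sample")
        bad = set(np.unique(self.group)) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if self.scale not in ("raw", "log"):
            raise ValueError("scale must be 'raw' or 'log'")

    @cached_property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_tumor(self) -> int:
        return int((self.group == "tumor").sum())

    @property
    def n_normal(self) -> int:
        return int((self.group == "normal").sum())

    def check_inclusion(self, min_per_group: int = 3) -> None:
        """Inclusion rule: at least 3 tumor and 3 normal samples."""
        if self.n_tumor < min_per_group or self.n_normal < min_per_group:
            raise ValueError(
                f"{self.dataset_id}: needs >= {min_per_group} samples per group "
                f"(has {self.n_tumor} tumor / {self.n_normal} normal)"
            )

    def values(self, gene: str, group: str | None = None) -> np.ndarray:
        row = self.matrix[self.gene_index[gene]]
        if group is None:
            return row
        return row[self.group == group]


@dataclass(frozen=True)
class GeneSetCollection:
    """Mapping set_id -> (description, member gene ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]


def _sniff_delimiter(header_line: str) -> str:
    try:
        return csv.Sniffer().sniff(header_line, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t" if "\t" in header_line else ","


def read_expression_table(path: str | Path, orientation: str = "genes-rows") -> pd.DataFrame:
    """Read a delimited gene x sample (or transposed) expression table.

    The delimiter is sniffed from the header line (tab vs comma vs
    semicolon).  Duplicate row or column identifiers and non-numeric body
    cells raise with the offending identifier; NA cells stay NaN.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    delim = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=delim, index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate row identifier {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate column identifier {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path.name}: non-numeric value in column {col!r}, row {bad[0]!r}"
                )
            df[col] = coerced
    if orientation == "samples-rows":
        df = df.T
    elif orientation != "genes-rows":
        raise ValueError("orientation must be 'genes-rows' or 'samples-rows'")
    return df


def dataset_from_frames(
    expr: pd.DataFrame,
    pheno: pd.DataFrame,
    dataset_id: str,
    platform_id: str = "",
    scale: str = "log",
) -> ExpressionDataset:
    """Assemble a dataset from an expression frame and a phenotype frame.

    ``pheno`` needs columns sample_id and group; samples present in both
    tables are kept, in the expression table's order.
    """
    ph = pheno.set_index("sample_id")
    keep = [s for s in expr.columns if s in ph.index]
    if not keep:
        raise ValueError(f"{dataset_id}: no overlap between expression and phenotype samples")
    expr = expr[keep]
    group = ph.loc[keep, "group"].to_numpy(dtype=object)
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform_id=platform_id or dataset_id,
        matrix=expr.to_numpy(dtype=float),
        gene_ids=tuple(expr.index.astype(str)),
        sample_ids=tuple(keep),
        group=np.asarray(group, dtype=object),
        scale=scale,
    )


def write_expression_table(ds: ExpressionDataset, path: str | Path) -> None:
    df = pd.DataFrame(ds.matrix, index=list(ds.gene_ids), columns=list(ds.sample_ids))
    df.to_csv(path, sep="\t", index_label="gene_id")


def log_scale(ds: ExpressionDataset, pseudo: float = LOG_PSEUDOCOUNT) -> ExpressionDataset:
    """log2(x + pseudo) transform of a raw-scale dataset."""
    if ds.scale != "raw":
        raise ValueError(f"{ds.dataset_id}: already on the log scale")
    if np.nanmin(ds.matrix) < 0:
        raise ValueError(f"{ds.dataset_id}: negative values cannot be raw abundances")
    return replace(ds, matrix=np.log2(ds.matrix + pseudo), scale="log")


def auto_log(ds: ExpressionDataset) -> ExpressionDataset:
    """Apply log_scale only when values look like raw abundances.

    Heuristic: the 99th percentile of finite values above 50 indicates raw
    TPM/intensity data (log2-scale expression essentially never reaches
    that).  Idempotent; the decision is logged.
    """
    q = float(np.nanpercentile(ds.matrix, AUTO_LOG_PERCENTILE))
    if ds.scale == "raw" and q > AUTO_LOG_THRESHOLD:
        logger.info("auto_log: %s p99=%.1f -> log2(x+%g)", ds.dataset_id, q, LOG_PSEUDOCOUNT)
        return log_scale(ds)
    logger.info("auto_log: %s p99=%.1f -> unchanged", ds.dataset_id, q)
    if ds.scale == "raw" and q <= AUTO_LOG_THRESHOLD:
        # values already log-like; relabel without transforming
        return replace(ds, scale="log")
    return ds


def impute_missing(ds: ExpressionDataset, max_missing_frac: float = 0.2) -> ExpressionDataset:
    """Gene-median imputation; genes missing in > max_missing_frac dropped."""
    mat = ds.matrix
    miss = np.isnan(mat)
    if not miss.any():
        return ds
    frac = miss.mean(axis=1)
    keep = frac <= max_missing_frac
    dropped = int((~keep).sum())
    if dropped:
        logger.info("impute_missing: %s dropped %d genes (> %.0f%% missing)",
                    ds.dataset_id, dropped, 100 * max_missing_frac)
    mat = mat[keep].copy()
    med = np.nanmedian(mat, axis=1)
    idx = np.where(np.isnan(mat))
    mat[idx] = med[idx[0]]
    return replace(ds, matrix=mat, gene_ids=tuple(g for g, k in zip(ds.gene_ids, keep) if k))


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample to the common rank-mean value distribution.

    Each sample's sorted values are replaced by the mean of sorted values
    across samples, assigned back by within-sample rank (ties receive the
    average of the tied reference values).  Constant samples are left in
    place with a warning.
    """
    if ds.scale != "log":
        raise ValueError("quantile_normalize expects log-scale data")
    mat = ds.matrix
    if np.isnan(mat).any():
        raise ValueError("impute missing values before quantile normalization")
    const = mat.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{ds.dataset_id}: {int(const.sum())} constant sample(s) left in place"
        )
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    ng = mat.shape[0]
    for j in range(mat.shape[1]):
        ranks = stats.rankdata(mat[:, j], method="average")  # 1..ng, ties averaged
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (ref[lo] + ref[hi])
    return replace(ds, matrix=out)


def merge_platform(
    datasets: Sequence[ExpressionDataset], *, batch_correct: str = "center"
) -> ExpressionDataset:
    """Concatenate same-platform cohorts on their shared genes.

    Batch correction ('center') shifts each gene's per-source-dataset mean
    to the pooled gene mean, computed on tumor and normal samples jointly —
    a location-only adjustment that cannot fabricate group effects.  Source
    provenance is retained in ``batch``.
    """
    if len(datasets) < 2:
        raise ValueError("merge_platform needs at least two datasets")
    platforms = {d.platform_id for d in datasets}
    if len(platforms) != 1:
        raise ValueError(f"datasets span multiple platforms: {sorted(platforms)}")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset_id in merge")
    shared = set(datasets[0].gene_ids)
    for d in datasets[1:]:
        shared &= set(d.gene_ids)
    if not shared:
        counts = {d.dataset_id: len(d.gene_ids) for d in datasets}
        raise ValueError(f"empty gene intersection; per-dataset gene counts: {counts}")
    genes = sorted(shared)
    blocks, groups, samples, batch = [], [], [], []
    for d in datasets:
        idx = [d.gene_index[g] for g in genes]
        blocks.append(d.matrix[idx])
        groups.append(d.group)
        samples.extend(f"{d.dataset_id}:{s}" for s in d.sample_ids)
        batch.extend([d.dataset_id] * len(d.sample_ids))
    mat = np.concatenate(blocks, axis=1)
    if batch_correct == "center":
        pooled_mean = mat.mean(axis=1, keepdims=True)
        col = 0
        for b in blocks:
            nb = b.shape[1]
            mat[:, col : col + nb] += pooled_mean - b.mean(axis=1, keepdims=True)
            col += nb
    elif batch_correct != "off":
        raise ValueError("batch_correct must be 'center' or 'off'")
    return ExpressionDataset(
        dataset_id="+".join(ids),
        platform_id=datasets[0].platform_id,
        matrix=mat,
        gene_ids=tuple(genes),
        sample_ids=tuple(samples),
        group=np.concatenate(groups),
        scale="log",
        batch=tuple(batch),
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT v1 gene-set file (set_id TAB description TAB members...)."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno} has fewer than 3 fields")
            set_id, desc = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    warnings.warn(f"{path}: duplicate member {m!r} in set {set_id}")
                    continue
                seen.add(m)
                members.append(m)
            sets[set_id] = (desc, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(gene_sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in gene_sets.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")
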
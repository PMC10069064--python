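"""Per-gene mutation-frequency screen from per-sample variant calls.

Frequency = fraction of samples carrying at least one retained SNV in the
gene; the high-frequency filter keeps genes at or above a threshold
(default 5%), ranked by frequency.  Calls arrive as a minimal VCF subset
(CHROM/POS/REF/ALT with the sample in an INFO-free sample column or a
SAMPLE info key) or a flat TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

VARIANT_COLUMNS = ("sample_id", "gene", "chrom", "pos", "ref", "alt")


@dataclass(frozen=True)
class VariantTable:
    """Normalized per-sample SNV records."""

    records: pd.DataFrame  # columns VARIANT_COLUMNS

    def __post_init__(self) -> None:
        df = self.records
        missing = set(VARIANT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        if len(df):
            if (df["pos"] < 1).any():
                raise ValueError("positions are 1-based; pos must be >= 1")
            if (df["ref"] == df["alt"]).any():
                raise ValueError("ref and alt alleles must differ")
            dup = df.duplicated(subset=["sample_id", "chrom", "pos", "alt"])
            if dup.any():
                row = df[dup].iloc[0]
                raise ValueError(
                    f"duplicate call: {row.sample_id} {row.chrom}:{row.pos} {row.alt}"
                )

    def __len__(self) -> int:
        return len(self.records)


def _parse_vcf(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path.name}: malformed VCF line {lineno}")
            chrom, pos, _id, ref, alts, _qual, _filt, info = fields[:8]
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            sample = kv.get("SAMPLE")
            gene = kv.get("GENE")
            if sample is None or gene is None:
                raise ValueError(
                    f"{path.name}: line {lineno} lacks SAMPLE=/GENE= INFO keys"
                )
            for alt in alts.split(","):  # multi-allelic: one record per alt
                rows.append((sample, gene, chrom, int(pos), ref, alt))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def _parse_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    df = df[list(VARIANT_COLUMNS)].copy()
    df["pos"] = df["pos"].astype(int)
    return df


def read_variants(path: str | Path, format: str | None = None) -> VariantTable:
    """Read SNV calls from a minimal VCF or a flat TSV.

    The format is inferred from the suffix when not given; multi-allelic
    VCF ALT fields are split into one record per alternate allele.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "vcf":
        df = _parse_vcf(path)
    elif format == "tsv":
        df = _parse_tsv(path)
    else:
        raise ValueError(f"unknown variant format: {format!r}")
    df = df.sort_values(["sample_id", "chrom", "pos", "alt"], kind="stable").reset_index(
        drop=True
    )
    return VariantTable(df)


def write_variants_vcf(table: VariantTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in table.records.itertuples():
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"SAMPLE={r.sample_id};GENE={r.gene}\n"
            )


def gene_mutation_frequency(
    table: VariantTable,
    sample_roster: Sequence[str],
    cancer_gene_list: Iterable[str] | None = None,
) -> dict[str, float]:
    """Fraction of roster samples with >= 1 retained SNV per gene.

    Multiple SNVs in the same gene and sample count once.  When a cancer
    gene list is supplied, calls outside it are dropped before counting.
    Samples in the table but absent from the roster are an error.
    """
    roster = list(sample_roster)
    if len(roster) < 1:
        raise ValueError("sample roster must be non-empty")
    df = table.records
    unknown = set(df["sample_id"]) - set(roster)
    if unknown:
        raise ValueError(f"samples not in roster: {sorted(unknown)[:5]}")
    if cancer_gene_list is not None:
        keep = set(cancer_gene_list)
        df = df[df["gene"].isin(keep)]
    n = len(roster)
    counts = df.drop_duplicates(subset=["sample_id", "gene"]).groupby("gene").size()
    return {gene: c / n for gene, c in counts.items()}


def high_frequency_genes(
    freqs: Mapping[str, float], threshold: float = 0.05, top_n: int | None = None
) -> list[tuple[str, float]]:
    """Genes at or above the frequency threshold, ranked.

    Sorted by frequency descending, ties broken lexicographically; the
    threshold is inclusive (a gene at exactly 5% is retained).
    """
    if any(not (0 <= f <= 1) for f in freqs.values()):
        raise ValueError("frequencies must lie in [0, 1]")
    kept = [(g, f) for g, f in freqs.items() if f >= threshold]
    kept.sort(key=lambda gf: (-gf[1], gf[0]))
    return kept[:top_n] if top_n is not None else kept
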
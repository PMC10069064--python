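"""End-to-end orchestration: ingest -> normalize/merge -> SMD -> SROC ->
survival -> co-expression/enrichment -> immune -> clinical -> variants.

``run_all`` executes every stage whose inputs are present in the config,
writes one TSV per stage plus a JSON manifest (config echo, seed, output
checksums), and ``report`` renders the bundle as a human-readable summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import clinical as clin
from . import coexpression as coex
from . import diagnostics as diag
from . import effects, immune, ingest
from . import survival as surv
from . import variants as var

logger = logging.getLogger("oscmeta")

FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Validated pipeline configuration (flat key=value file or kwargs)."""

    out_dir: str = "oscmeta_out"
    seed: int = 0
    target_gene: str = "TARGET"
    expression_dir: str | None = None
    phenotype: str | None = None
    survival: str | None = None
    gene_sets: str | None = None
    fractions: str | None = None
    clinical: str | None = None
    variants: str | None = None
    variant_roster: str | None = None
    cancer_genes: str | None = None
    alpha: float = 0.05
    lfc_min: float = 1.0
    up_min_datasets: int = 7
    down_min_datasets: int = 5
    mutation_threshold: float = 0.05
    dichotomize: str = "youden"  # youden | median
    model: str = "dl"  # dl | fixed
    unit: str = "platform"  # platform | dataset
    batch_correct: str = "center"  # center | off
    correlation: str = "pearson"  # pearson | spearman

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")
        if not 0 <= self.mutation_threshold <= 1:
            raise ValueError("mutation_threshold must lie in [0, 1]")
        if self.dichotomize not in ("youden", "median"):
            raise ValueError("dichotomize must be 'youden' or 'median'")
        if self.model not in ("dl", "fixed"):
            raise ValueError("model must be 'dl' or 'fixed'")
        if self.unit not in ("platform", "dataset"):
            raise ValueError("unit must be 'platform' or 'dataset'")
        for key in ("expression_dir", "phenotype", "survival", "gene_sets",
                    "fractions", "clinical", "variants", "variant_roster",
                    "cancer_genes"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Parse a flat key=value config file; CLI overrides win."""
        kwargs: dict[str, Any] = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: line {lineno} is not key=value")
                key, val = (s.strip() for s in line.split("=", 1))
                if key not in types:
                    raise ValueError(f"{path}: unknown config key {key!r}")
                kwargs[key] = val
        for k in ("seed", "up_min_datasets", "down_min_datasets"):
            if k in kwargs:
                kwargs[k] = int(kwargs[k])
        for k in ("alpha", "lfc_min", "mutation_threshold"):
            if k in kwargs:
                kwargs[k] = float(kwargs[k])
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_cohorts(config: RunConfig) -> list[ingest.ExpressionDataset]:
    pheno = pd.read_csv(config.phenotype, sep="\t", dtype={"sample_id": str})
    cohorts = []
    for path in sorted(Path(config.expression_dir).glob("*.tsv")):
        dsid = path.stem
        sub = pheno[pheno["dataset_id"] == dsid]
        if sub.empty:
            logger.warning("no phenotype rows for %s; skipped", dsid)
            continue
        platform = str(sub["platform_id"].iloc[0]) if "platform_id" in sub else dsid
        expr = ingest.read_expression_table(path)
        ds = ingest.dataset_from_frames(expr, sub, dsid, platform, scale="raw")
        ds = ingest.auto_log(ds)
        ds = ingest.impute_missing(ds)
        ds = ingest.quantile_normalize(ds)
        ds.check_inclusion()
        cohorts.append(ds)
    if not cohorts:
        raise ValueError("no usable expression cohorts found")
    return cohorts


def _analysis_units(
    cohorts: list[ingest.ExpressionDataset], config: RunConfig
) -> list[ingest.ExpressionDataset]:
    if config.unit == "dataset":
        return cohorts
    by_platform: dict[str, list[ingest.ExpressionDataset]] = {}
    for ds in cohorts:
        by_platform.setdefault(ds.platform_id, []).append(ds)
    units = []
    for platform, group in sorted(by_platform.items()):
        if len(group) == 1:
            units.append(group[0])
        else:
            units.append(ingest.merge_platform(group, batch_correct=config.batch_correct))
    return units


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage with available inputs; write TSVs + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {"config": config}
    stage_times: dict[str, float] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    def run_stage(name: str, fn) -> None:
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # halt with stage name, keep partial outputs
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        stage_times[name] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", name, stage_times[name])

    if config.expression_dir and config.phenotype:

        def stage_expression() -> None:
            cohorts = _load_cohorts(config)
            units = _analysis_units(cohorts, config)
            bundle["units"] = units

            # per-gene SMD records across units
            per_gene: dict[str, list[effects.EffectSizeRecord]] = {}
            target_records = []
            tables = []
            for ds in units:
                tum = ds.matrix[:, ds.group == "tumor"]
                nor = ds.matrix[:, ds.group == "normal"]
                g, v = effects.hedges_g_matrix(tum, nor)
                for gene, gi, vi in zip(ds.gene_ids, g, v):
                    if np.isfinite(gi):
                        half = effects.Z95 * np.sqrt(vi)
                        per_gene.setdefault(gene, []).append(
                            effects.EffectSizeRecord(
                                ds.dataset_id, float(gi), float(vi),
                                float(gi - half), float(gi + half),
                                tum.shape[1], nor.shape[1],
                            )
                        )
                t_vals = ds.values(config.target_gene, "tumor")
                n_vals = ds.values(config.target_gene, "normal")
                target_records.append(effects.hedges_g(t_vals, n_vals, ds.dataset_id))
                tables.append(
                    diag.youden_2x2(t_vals, n_vals, ds.dataset_id, rule=config.dichotomize)
                )
            pooled_target = effects.pool_dl(target_records, model=config.model)
            bundle["smd_pooled"] = pooled_target
            forest = effects.forest_table(target_records, pooled_target)
            save("smd_forest", forest)

            pooled_by_gene = effects.pool_genes(per_gene, model=config.model)
            degs_up, degs_down = effects.call_degs_by_smd(pooled_by_gene)
            bundle["degs_up"], bundle["degs_down"] = degs_up, degs_down
            save(
                "degs",
                pd.DataFrame(
                    {
                        "gene": sorted(degs_up) + sorted(degs_down),
                        "direction": ["up"] * len(degs_up) + ["down"] * len(degs_down),
                    }
                ),
            )

            # diagnostics
            se_pool = diag.pool_logit([(t.tp, t.tp + t.fn) for t in tables])
            sp_pool = diag.pool_logit([(t.tn, t.tn + t.fp) for t in tables])
            dlr_pos, dlr_neg = diag.pool_dlr(tables)
            fit = diag.fit_sroc(tables)
            bundle["sroc"] = fit
            bundle["pooled_se"], bundle["pooled_sp"] = se_pool, sp_pool
            bundle["dlr_pos"], bundle["dlr_neg"] = dlr_pos, dlr_neg
            save(
                "diagnostics",
                pd.DataFrame(
                    [
                        {
                            "dataset_id": t.dataset_id,
                            "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
                            "threshold": t.threshold,
                            "sensitivity": t.sensitivity,
                            "specificity": t.specificity,
                        }
                        for t in tables
                    ]
                ),
            )
            save("sroc_curve", pd.DataFrame({"fpr": fit.fpr, "tpr": fit.tpr}))

            # co-expression + enrichment; correlations are voted across the
            # individual datasets, not the merged platform units
            corr_by_ds = {
                ds.dataset_id: coex.correlate_target(
                    ds, config.target_gene, method=config.correlation
                )
                for ds in cohorts
            }
            pos, neg = coex.vote_count_coexpression(
                corr_by_ds, degs_up, degs_down,
                config.up_min_datasets, config.down_min_datasets, config.alpha,
            )
            bundle["coexpr_pos"], bundle["coexpr_neg"] = pos, neg
            save(
                "coexpression",
                pd.DataFrame(
                    {
                        "gene": sorted(pos) + sorted(neg),
                        "direction": ["positive"] * len(pos) + ["negative"] * len(neg),
                    }
                ),
            )
            if config.gene_sets:
                sets = ingest.read_gmt(config.gene_sets)
                universe = sorted(set(units[0].gene_ids))
                enr = coex.hypergeom_enrich(pos | neg, sets, universe)
                bundle["enrichment"] = enr
                save("enrichment", coex.enrichment_frame(enr))

        run_stage("expression", stage_expression)

    if config.survival:

        def stage_survival() -> None:
            tab = pd.read_csv(config.survival, sep="\t")
            records = []
            for cohort_id, sub in tab.groupby("cohort_id"):
                split = surv.median_split(sub)
                records.append(surv.logrank_hr(split, str(cohort_id)))
            pooled = surv.pool_hr(records, model=config.model)
            bundle["hr_records"], bundle["hr_pooled"] = records, pooled
            rows = [
                {
                    "cohort_id": r.cohort_id, "hr": r.hr, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "log_hr": r.log_hr, "se": r.se, "p": r.p,
                }
                for r in records
            ]
            rows.append(
                {
                    "cohort_id": "POOLED", "hr": pooled["hr"],
                    "ci_low": pooled["ci_low"], "ci_high": pooled["ci_high"],
                    "log_hr": pooled["log_hr"], "se": pooled["se"], "p": np.nan,
                }
            )
            save("survival_hr", pd.DataFrame(rows))

        run_stage("survival", stage_survival)

    if config.fractions:

        def stage_immune() -> None:
            frac = pd.read_csv(config.fractions, sep="\t", index_col=0)
            frac = frac.drop(columns=["true_group"], errors="ignore")
            immune.validate_fractions(frac)
            grouped = immune.split_by_median_expression(frac)
            res = immune.per_celltype_test(grouped)
            bundle["immune"] = res
            save("immune", res)

        run_stage("immune", stage_immune)

    if config.clinical:

        def stage_clinical() -> None:
            tab = pd.read_csv(config.clinical, sep="\t")
            if "score" in tab.columns and "positive" not in tab.columns:
                tab["positive"] = clin.ihc_dichotomize(tab["score"].to_numpy())
            strata = [
                c for c in tab.columns
                if c not in ("patient_id", "score", "positive")
            ]
            res = clin.clinical_association_table(tab, strata)
            bundle["clinical"] = res
            save("clinical", res)

        run_stage("clinical", stage_clinical)

    if config.variants:

        def stage_variants() -> None:
            vt = var.read_variants(config.variants)
            if config.variant_roster:
                roster = Path(config.variant_roster).read_text().split()
            else:
                roster = sorted(vt.records["sample_id"].unique())
            genes = None
            if config.cancer_genes:
                genes = Path(config.cancer_genes).read_text().split()
            freqs = var.gene_mutation_frequency(vt, roster, genes)
            ranked = var.high_frequency_genes(freqs, config.mutation_threshold)
            bundle["mutation_freqs"] = freqs
            bundle["high_freq_genes"] = ranked
            save(
                "variants",
                pd.DataFrame(ranked, columns=["gene", "frequency"]),
            )

        run_stage("variants", stage_variants)

    if len(bundle) == 1:
        raise ValueError("config provides no stage inputs; nothing to run")

    manifest = {
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "stages": sorted(stage_times),
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    bundle["manifest"] = manifest
    return bundle


def report(bundle: dict[str, Any]) -> str:
    """Human-readable summary of a completed bundle (pure function)."""
    known = {"smd_pooled", "sroc", "hr_pooled", "immune", "clinical",
             "high_freq_genes", "coexpr_pos", "enrichment"}
    if not known & set(bundle):
        raise ValueError("bundle is empty; run at least one stage first")
    lines = ["oscmeta run summary", "===================="]
    if "smd_pooled" in bundle:
        p = bundle["smd_pooled"]
        lines.append(
            f"Pooled SMD (target gene): {p.pooled_g:.3f} "
            f"[{p.ci_low:.3f}, {p.ci_high:.3f}]  (k={p.k}, I2={100 * p.I2:.0f}%)"
        )
        lines.append(
            f"Final DEGs by CI sign: {len(bundle.get('degs_up', ()))} up, "
            f"{len(bundle.get('degs_down', ()))} down"
        )
    if "sroc" in bundle:
        fit = bundle["sroc"]
        se, (se_lo, se_hi) = bundle["pooled_se"]
        sp, (sp_lo, sp_hi) = bundle["pooled_sp"]
        dlr_p, dlr_p_ci = bundle["dlr_pos"]
        dlr_n, dlr_n_ci = bundle["dlr_neg"]
        lines.append(f"Summary SROC AUC: {fit.auc:.3f}")
        lines.append(f"Pooled sensitivity: {se:.3f} [{se_lo:.3f}, {se_hi:.3f}]")
        lines.append(f"Pooled specificity: {sp:.3f} [{sp_lo:.3f}, {sp_hi:.3f}]")
        lines.append(
            f"Pooled DLR+: {dlr_p:.2f} [{dlr_p_ci[0]:.2f}, {dlr_p_ci[1]:.2f}]; "
            f"DLR-: {dlr_n:.2f} [{dlr_n_ci[0]:.2f}, {dlr_n_ci[1]:.2f}]"
        )
    if "coexpr_pos" in bundle:
        lines.append(
            f"Co-expressed with target: {len(bundle['coexpr_pos'])} positive, "
            f"{len(bundle['coexpr_neg'])} negative"
        )
    if "enrichment" in bundle and bundle["enrichment"]:
        top = bundle["enrichment"][:3]
        terms = "; ".join(f"{e.set_id} (p={e.p:.2e})" for e in top)
        lines.append(f"Top enriched sets: {terms}")
    if "hr_pooled" in bundle:
        h = bundle["hr_pooled"]
        lines.append(
            f"Pooled HR (high vs low): {h['hr']:.2f} "
            f"[{h['ci_low']:.2f}, {h['ci_high']:.2f}]  (k={h['k']})"
        )
    if "immune" in bundle:
        sig = bundle["immune"][bundle["immune"]["significant"]]
        lines.append(
            f"Immune cell types differing by marker group (p<0.05): {len(sig)}"
            + (f" — {', '.join(sig['cell_type'].head(5))}" if len(sig) else "")
        )
    if "clinical" in bundle:
        sig = bundle["clinical"].drop_duplicates(subset=["variable"])
        assoc = sig[sig["p_overall"] < 0.05]["variable"].tolist()
        lines.append(f"Clinical variables associated with positivity: {assoc or 'none'}")
    if "high_freq_genes" in bundle:
        top = bundle["high_freq_genes"][:10]
        lines.append(
            "Top mutated genes: "
            + ", ".join(f"{g} ({f:.1%})" for g, f in top)
        )
    return "\n".join(lines) + "\n"
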
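"""Synthetic cohorts with known ground truth for every pipeline stage.

The expression generator emulates a multi-platform case/control compendium:
each cohort shares gene identifiers and per-gene baselines, carries its own
batch location shift, and embeds (a) a target gene with a true standardized
mean difference and (b) latent-factor co-expression blocks tied to the
target.  Companion generators produce exponential survival with an
expression-linked hazard, Dirichlet immune-cell fractions, Bernoulli
per-gene mutation tables, and patient-level clinical tables.

Everything is deterministic given (spec, seed); per-cohort seeds are split
from a root seed by hashing the dataset id, so adding a cohort never
perturbs the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .ingest import ExpressionDataset

TARGET_GENE = "TARGET"

#: CIBERSORT LM22 panel names, used as the default immune cell types.
LM22_CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells", "T cells CD8",
    "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta", "NK cells resting",
    "NK cells activated", "Monocytes", "Macrophages M0", "Macrophages M1",
    "Macrophages M2", "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated", "Eosinophils", "Neutrophils",
)


def split_seed(root_seed: int, label: str) -> int:
    """Deterministic sub-seed below 2^31 from a root seed and a label."""
    digest = hashlib.sha256(f"{label}:{root_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class CohortSpec:
    """Design of one simulated case/control expression cohort."""

    dataset_id: str
    platform_id: str
    n_tumor: int
    n_normal: int
    n_genes: int
    target_effect: float = 0.0  # true SMD of the target gene
    block_genes: int = 0  # genes sharing the latent factor with the target
    block_loading: float = 0.0  # latent-factor loading in [0, 1]
    batch_shift: float = 0.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ValueError("need at least 2 tumor and 2 normal samples")
        if self.n_genes <= self.block_genes:
            raise ValueError("block_genes must be smaller than n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.block_loading <= 1:
            raise ValueError("block_loading must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth matching a set of generated datasets."""

    target_gene: str
    gene_effects: dict[str, float]  # true SMD per gene
    pos_block: set[str] = field(default_factory=set)
    neg_block: set[str] = field(default_factory=set)
    survival_log_hazard: float | None = None
    alpha_low: np.ndarray | None = None
    alpha_high: np.ndarray | None = None
    mutation_probs: dict[str, float] | None = None


def _gene_design(
    n_genes: int, block_genes: int, target_effect: float, block_loading: float
) -> tuple[list[str], np.ndarray, np.ndarray, set[str], set[str]]:
    """Shared per-gene truth: names, true SMDs delta_g, loadings lambda_g.

    Gene 0 is the target.  The co-expression block splits evenly into a
    positive half (loading +lambda, delta +0.8) and a negative half
    (loading -lambda, delta -0.8).  A further 10% of the remaining genes
    are differential but unloaded (alternating delta = +/-0.8), the rest
    are null — so DEG status and co-expression status can disagree, as in
    real compendia.
    """
    genes = [TARGET_GENE] + [f"G{i:04d}" for i in range(1, n_genes)]
    delta = np.zeros(n_genes)
    lam = np.zeros(n_genes)
    delta[0] = target_effect
    lam[0] = block_loading
    n_pos = block_genes // 2 + block_genes % 2
    pos = set(genes[1 : 1 + n_pos])
    neg = set(genes[1 + n_pos : 1 + block_genes])
    delta[1 : 1 + n_pos] = 0.8
    lam[1 : 1 + n_pos] = block_loading
    delta[1 + n_pos : 1 + block_genes] = -0.8
    lam[1 + n_pos : 1 + block_genes] = -block_loading
    n_deg_only = (n_genes - 1 - block_genes) // 10
    start = 1 + block_genes
    signs = np.where(np.arange(n_deg_only) % 2 == 0, 0.8, -0.8)
    delta[start : start + n_deg_only] = signs
    return genes, delta, lam, pos, neg


def gen_expression_cohorts(
    specs: Sequence[CohortSpec], *, as_raw: bool = False
) -> tuple[list[ExpressionDataset], SimTruth]:
    """Generate case/control cohorts with a shared true target effect.

    Model per gene g and sample j:
      x_gj = mu_g + batch_shift + delta_g * sd_g * 1[tumor]
             + lambda_g * f_j * noise_sd + eps_gj,
    with f_j a standard-normal latent factor shared by the target and
    block genes, eps ~ N(0, noise_sd^2), and sd_g = noise_sd *
    sqrt(1 + lambda_g^2) the gene's total SD — so delta_g is the gene's
    true standardized mean difference exactly.  Per-gene baselines mu_g
    are shared across cohorts.  ``as_raw=True`` exponentiates (2^x) to
    mimic raw-intensity input for the auto-log heuristic.
    """
    if len(specs) == 0:
        raise ValueError("need at least one cohort spec")
    ids = [s.dataset_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset_id in cohort specs")
    ref = specs[0]
    genes, delta, lam, pos, neg = _gene_design(
        ref.n_genes, ref.block_genes, ref.target_effect, ref.block_loading
    )
    # baselines shared across cohorts: fixed stream independent of cohort seeds
    mu = stats.norm.rvs(
        loc=8.0, scale=2.0, size=ref.n_genes,
        random_state=np.random.default_rng(split_seed(ref.seed, "baselines")),
    )
    datasets = []
    for spec in specs:
        if (spec.n_genes, spec.block_genes) != (ref.n_genes, ref.block_genes):
            raise ValueError("all cohorts must share the gene design")
        rng = np.random.default_rng(split_seed(spec.seed, spec.dataset_id))
        n = spec.n_tumor + spec.n_normal
        is_tumor = np.zeros(n, dtype=bool)
        is_tumor[: spec.n_tumor] = True
        f = rng.standard_normal(n)
        eps = rng.standard_normal((spec.n_genes, n)) * spec.noise_sd
        sd_g = spec.noise_sd * np.sqrt(1.0 + lam**2)
        mat = (
            mu[:, None]
            + spec.batch_shift
            + np.outer(delta * sd_g, is_tumor.astype(float))
            + np.outer(lam * spec.noise_sd, f)
            + eps
        )
        scale = "log"
        if as_raw:
            mat = np.power(2.0, mat)
            scale = "raw"
        datasets.append(
            ExpressionDataset(
                dataset_id=spec.dataset_id,
                platform_id=spec.platform_id,
                matrix=mat,
                gene_ids=tuple(genes),
                sample_ids=tuple(
                    f"{spec.dataset_id}_S{j:03d}" for j in range(n)
                ),
                group=np.where(is_tumor, "tumor", "normal").astype(object),
                scale=scale,
            )
        )
    truth = SimTruth(
        target_gene=TARGET_GENE,
        gene_effects=dict(zip(genes, delta.tolist())),
        pos_block=pos,
        neg_block=neg,
    )
    return datasets, truth


def _solve_censor_horizon(beta: float, baseline_rate: float, censor_rate: float) -> float:
    """Horizon T_max for uniform(0, T_max) censoring hitting the target rate.

    P(censored | z) = (1 - exp(-rate(z) T)) / (rate(z) T) for C ~ U(0, T);
    averaged over z ~ N(0,1) on a quantile grid and solved for T.
    """
    z = stats.norm.ppf(np.linspace(0.001, 0.999, 199))
    rates = baseline_rate * np.exp(beta * z)

    def expected_censoring(T: float) -> float:
        lt = rates * T
        return float(np.mean((1.0 - np.exp(-lt)) / lt))

    # expected_censoring decreases from 1 (T->0) to 0 (T->inf)
    lo, hi = 1e-9, 1e12
    return float(optimize.brentq(lambda T: expected_censoring(T) - censor_rate, lo, hi))


def gen_survival_cohort(
    n: int,
    beta: float,
    baseline_rate: float = 0.1,
    censor_rate: float = 0.0,
    seed: int = 0,
    cohort_id: str = "sim",
) -> pd.DataFrame:
    """Exponential survival with hazard baseline_rate * exp(beta * z).

    z is the patient's standardized target-gene expression.  Censoring is
    independent uniform on (0, T_max), with T_max solved numerically so the
    expected censoring fraction equals ``censor_rate``; 0 means none.
    Returns a table with columns cohort_id, sample_id, time, event,
    expression.
    """
    if n < 10:
        raise ValueError("need at least 10 patients")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must lie in [0, 1)")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    rng = np.random.default_rng(split_seed(seed, f"survival:{cohort_id}"))
    z = rng.standard_normal(n)
    rate = baseline_rate * np.exp(beta * z)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        tmax = _solve_censor_horizon(beta, baseline_rate, censor_rate)
        c = rng.uniform(0.0, tmax, size=n)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    return pd.DataFrame(
        {
            "cohort_id": cohort_id,
            "sample_id": [f"{cohort_id}_P{i:04d}" for i in range(n)],
            "time": time,
            "event": event,
            "expression": z,
        }
    )


def gen_immune_fractions(
    n: int,
    celltypes: Sequence[str] = LM22_CELL_TYPES,
    alpha_low: Sequence[float] | None = None,
    alpha_high: Sequence[float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet immune-cell fractions for a low and a high expression group.

    ``n`` samples per group; each row is Dirichlet with its group's
    concentration vector (default: flat alpha = 2).  An ``expression``
    column is emitted such that a median split recovers the groups (low
    group uniform on (0,1), high on (1,2)).
    """
    k = len(celltypes)
    alpha_low = np.full(k, 2.0) if alpha_low is None else np.asarray(alpha_low, float)
    alpha_high = np.full(k, 2.0) if alpha_high is None else np.asarray(alpha_high, float)
    if alpha_low.size != k or alpha_high.size != k:
        raise ValueError("concentration vectors must match the cell-type list")
    if np.any(alpha_low <= 0) or np.any(alpha_high <= 0):
        raise ValueError("Dirichlet concentrations must be strictly positive")
    rng = np.random.default_rng(split_seed(seed, "immune"))
    low = rng.dirichlet(alpha_low, size=n)
    high = rng.dirichlet(alpha_high, size=n)
    df = pd.DataFrame(np.vstack([low, high]), columns=list(celltypes))
    df.insert(0, "sample_id", [f"I{i:04d}" for i in range(2 * n)])
    df["expression"] = np.concatenate(
        [rng.uniform(0, 1, size=n), rng.uniform(1, 2, size=n)]
    )
    df["true_group"] = ["low"] * n + ["high"] * n
    return df


_BASES = np.array(list("ACGT"))


def gen_variant_table(
    n_samples: int, gene_probs: Mapping[str, float], seed: int = 0
) -> pd.DataFrame:
    """Bernoulli per-gene mutation calls over a sample roster.

    Each sample carries a mutation in gene g with probability
    ``gene_probs[g]``; positions are deterministic per (gene, sample) so
    records are unique.  Returns the flat variant TSV schema
    (sample_id, gene, chrom, pos, ref, alt).
    """
    if any(not (0 <= p <= 1) for p in gene_probs.values()):
        raise ValueError("mutation probabilities must lie in [0, 1]")
    rng = np.random.default_rng(split_seed(seed, "variants"))
    samples = [f"M{i:03d}" for i in range(n_samples)]
    rows = []
    for gi, (gene, prob) in enumerate(sorted(gene_probs.items())):
        hits = rng.random(n_samples) < prob
        chrom = f"chr{gi % 19 + 1}"
        base_pos = 1_000_000 * (gi + 1)
        for si in np.nonzero(hits)[0]:
            ref, alt = rng.choice(_BASES, size=2, replace=False)
            rows.append((samples[si], gene, chrom, base_pos + int(si), ref, alt))
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "chrom", "pos", "ref", "alt"]
    )


def gen_clinical_table(
    strata: Mapping[str, tuple[int, float]], seed: int = 0
) -> pd.DataFrame:
    """Patient-level table: one row per patient, stratum label + positivity.

    ``strata`` maps stratum name -> (n patients, positivity probability).
    """
    rng = np.random.default_rng(split_seed(seed, "clinical"))
    rows = []
    pid = 0
    for stratum, (n, prob) in strata.items():
        if n < 1:
            raise ValueError(f"stratum {stratum!r} needs at least 1 patient")
        flags = rng.random(n) < prob
        for f in flags:
            rows.append({"patient_id": f"C{pid:04d}", "stratum": stratum,
                         "positive": int(f)})
            pid += 1
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Default simulation profile: the standard study conditions used by the
# recovery suites — 18 cohorts over 6 platforms, 30 tumor / 30 normal
# each, true target SMD 0.9, a 60-gene co-expression block at loading 0.8.
# ----------------------------------------------------------------------

def default_profile(
    seed: int = 0,
    n_cohorts: int = 18,
    n_tumor: int = 30,
    n_normal: int = 30,
    n_genes: int = 400,
    target_effect: float = 0.9,
    block_genes: int = 60,
    block_loading: float = 0.8,
    noise_sd: float = 1.0,
) -> list[CohortSpec]:
    """Cohort specs for the default multi-platform profile.

    Platforms cycle through six labels (three cohorts each at the default
    size); batch shifts alternate in sign and grow with the cohort index
    to exercise the merge/centering stage.
    """
    specs = []
    for i in range(n_cohorts):
        specs.append(
            CohortSpec(
                dataset_id=f"DS{i + 1:02d}",
                platform_id=f"PLAT{i % 6 + 1}",
                n_tumor=n_tumor,
                n_normal=n_normal,
                n_genes=n_genes,
                target_effect=target_effect,
                block_genes=block_genes,
                block_loading=block_loading,
                batch_shift=((-1) ** i) * 0.4 * (i % 5),
                noise_sd=noise_sd,
                seed=seed,
            )
        )
    return specs


def write_default_bundle(out_dir: str, seed: int = 0) -> "Path":
    """Write a complete synthetic input bundle plus a ready run config.

    Produces everything ``pipeline.run_all`` consumes: per-cohort raw-scale
    expression TSVs, a phenotype table, four survival cohorts (log-hazard
    0.7 per SD of expression, 30% censoring), LM22-style immune fractions
    with five shifted components, an IHC-style clinical table, a Bernoulli
    variant table over 36 samples, and gene sets covering the planted
    co-expression blocks.  Returns the path of the written config file.
    """
    from pathlib import Path

    from .ingest import GeneSetCollection, write_expression_table, write_gmt

    out = Path(out_dir)
    (out / "expression").mkdir(parents=True, exist_ok=True)
    specs = default_profile(seed=seed)
    datasets, truth = gen_expression_cohorts(specs, as_raw=True)
    pheno_rows = []
    for spec, ds in zip(specs, datasets):
        write_expression_table(ds, out / "expression" / f"{ds.dataset_id}.tsv")
        for sid, grp in zip(ds.sample_ids, ds.group):
            pheno_rows.append(
                {"sample_id": sid, "group": grp,
                 "dataset_id": ds.dataset_id, "platform_id": ds.platform_id}
            )
    pd.DataFrame(pheno_rows).to_csv(out / "phenotype.tsv", sep="\t", index=False)

    surv_frames = [
        gen_survival_cohort(
            n=200, beta=0.7, baseline_rate=0.1, censor_rate=0.3,
            seed=seed, cohort_id=f"SURV{i + 1}",
        )
        for i in range(4)
    ]
    pd.concat(surv_frames).to_csv(out / "survival.tsv", sep="\t", index=False)

    k = len(LM22_CELL_TYPES)
    alpha_low = np.full(k, 2.0)
    alpha_high = alpha_low.copy()
    alpha_high[:5] *= 2.0  # five cell types enriched in the marker-high group
    frac = gen_immune_fractions(170, LM22_CELL_TYPES, alpha_low, alpha_high, seed=seed)
    frac.set_index("sample_id").to_csv(out / "fractions.tsv", sep="\t")

    clin_rows = []
    rng = np.random.default_rng(split_seed(seed, "clinical-covariates"))
    strata = {"N0": (23, 0.26), "N1": (37, 0.62), "N2": (23, 0.61)}
    tab = gen_clinical_table(strata, seed=seed)
    tab = tab.rename(columns={"stratum": "node_stage"})
    tab["pni"] = rng.choice(["PNI+", "PNI-"], size=len(tab), p=[0.35, 0.65])
    # emit raw IHC scores consistent with the positivity flags
    score = np.where(tab["positive"] == 1,
                     rng.integers(2, 4, size=len(tab)),
                     rng.integers(0, 2, size=len(tab)))
    tab["score"] = score
    tab.drop(columns=["positive"]).to_csv(out / "clinical.tsv", sep="\t", index=False)

    gene_probs = {"Cand01": 0.30, "Cand02": 0.20, "Cand03": 0.10,
                  "Cand04": 0.05, "Cand05": 0.02, "Cand06": 0.0}
    vt = gen_variant_table(36, gene_probs, seed=seed)
    vt.to_csv(out / "variants.tsv", sep="\t", index=False)
    (out / "variant_roster.txt").write_text(
        "\n".join(f"M{i:03d}" for i in range(36)) + "\n"
    )

    sets = GeneSetCollection(
        {
            "POS_BLOCK": ("planted positive co-expression block",
                          tuple(sorted(truth.pos_block))),
            "NEG_BLOCK": ("planted negative co-expression block",
                          tuple(sorted(truth.neg_block))),
            "RANDOM_SET": ("50 unrelated genes",
                           tuple(f"G{i:04d}" for i in range(200, 250))),
        }
    )
    write_gmt(sets, out / "gene_sets.gmt")

    config = out / "run.cfg"
    config.write_text(
        "\n".join(
            [
                f"out_dir = {out / 'results'}",
                f"seed = {seed}",
                f"target_gene = {TARGET_GENE}",
                f"expression_dir = {out / 'expression'}",
                f"phenotype = {out / 'phenotype.tsv'}",
                f"survival = {out / 'survival.tsv'}",
                f"gene_sets = {out / 'gene_sets.gmt'}",
                f"fractions = {out / 'fractions.tsv'}",
                f"clinical = {out / 'clinical.tsv'}",
                f"variants = {out / 'variants.tsv'}",
                f"variant_roster = {out / 'variant_roster.txt'}",
            ]
        )
        + "\n"
    )
    return config
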
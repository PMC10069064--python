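# Methods

This note documents the statistical models, defaults, and design choices
behind `oscmeta`, and what the synthetic-data tests do and do not show.

## Expression meta-analysis

Each cohort contributes a standardized mean difference for the
tumor-vs-normal contrast of a gene. "SMD" is implemented as **Hedges g**:
Cohen d on the df-weighted pooled SD, multiplied by the small-sample
correction J = 1 − 3/(4(n_T+n_N−2)−1), with the standard large-sample
variance var_g = (n_T+n_N)/(n_T n_N) + g²/(2(n_T+n_N)). This is the
convention of mainstream meta-analysis tooling; plain Cohen d is available
via `correct=False`.

Pooling is **DerSimonian–Laird random effects**: fixed weights w_i = 1/v_i
define Cochran's Q; the method-of-moments τ² = max(0, (Q−(k−1))/(Σw −
Σw²/Σw)) feeds random weights 1/(v_i+τ²). Fixed-effect pooling is the
τ²=0 special case (`model="fixed"`). All 95% intervals use the normal
quantile 1.96, matching conventional forest plots, not a t quantile.
k = 1 returns the single study with τ² = 0. Genes whose pooled SD is zero
in a cohort are skipped in that cohort only.

**DEG calling** is deliberately not a p-value threshold: a gene is up if
the pooled CI lower limit is > 0 and down if the upper limit is < 0.
This is the final selection rule of the workflow; the per-cohort Welch-t
screen in `prelim_de_screen` exists only as a preliminary filter, and a
plain Welch t + BH screen is used there rather than a moderated
(limma-style) fit because the final list is re-derived by the CI-sign
rule anyway. Cohorts may be pooled per dataset or per platform
(`unit=dataset|platform`); platform units are built by gene-wise
per-batch mean centering (below).

## Normalization and merging

Expression is analyzed on the log2(x + 0.001) scale. Ingest applies the
transform automatically when the 99th percentile of a cohort's values
exceeds 50 — raw TPM/intensity data essentially always exceeds that,
log2 data essentially never does; data already below the threshold is
relabelled as log-scale without transformation, making the heuristic
idempotent. Missing values get gene-median imputation; genes missing in
more than 20% of samples are dropped (counted in the log).

Quantile normalization forces every sample in a cohort to the common
rank-mean distribution (ties receive the average of the tied reference
values); it is idempotent and permutation-equivariant in samples.

Same-platform cohorts are merged on their shared genes with **location-only
batch correction**: each gene's per-source mean is shifted to the pooled
gene mean, computed on tumor and normal samples jointly. A location-only
adjustment cannot fabricate group effects (within-batch variances are
untouched), and downstream SMDs are scale-free within cohort; the
correction is configurable (`center | off`). Cross-platform combination is
always meta-analysis of per-unit effects, never matrix concatenation.

## Diagnostic meta-analysis

Per-cohort accuracy uses the Mann–Whitney AUC (ties count half) with the
Hanley–McNeil standard error. Continuous expression is dichotomized at the
**Youden-optimal threshold** (midpoints of sorted unique values, positive
if value ≥ threshold, ties broken toward higher sensitivity); a
median-split rule is available (`dichotomize=median`). Youden
optimization on the analysis data overfits slightly — per-study Se/Sp are
optimistic — which is accepted because the same rule is applied uniformly
across cohorts and the pooled summary is the object of interest.

Proportions are pooled on the logit scale by DL; studies containing a
zero cell get the 0.5 continuity correction on all four cells. Likelihood
ratios are pooled on the log scale with delta-method variances. The
summary ROC is a **bivariate normal random-effects model** on
(logit Se, logit Sp), estimated by maximum likelihood (Nelder–Mead on a
Cholesky-parameterized between-study covariance); the curve is the implied
regression of logit TPR on logit FPR and the summary AUC integrates it by
trapezoid over 1000 points. With fewer than 3 studies or on optimizer
failure the fit falls back to univariate DL pooling of the two logits with
zero covariance (flagged on the result); the Moses–Littenberg regression
is deliberately not used. Near-zero specificity variance degenerates the
curve to the horizontal line through the summary point.

## Survival meta-analysis

Patients are split at the **median** of the marker's expression, ties to
the low group (a deterministic rule shared with the immune module). The
Kaplan–Meier estimator processes events before censorings at tied times.
The per-cohort hazard ratio is the **log-rank (O−E)/V estimator**
(Peto-style): at each distinct event time the observed high-group events
are compared with the hypergeometric expectation; log HR = (O−E)/V,
se = 1/√V, χ² = (O−E)²/V on 1 df. This estimator — rather than a Cox
partial-likelihood fit — matches a workflow whose HRs are "derived from
the log-rank test"; it is consistent under proportional hazards and
attenuated otherwise, which is acceptable for pooling direction and
magnitude. Cohort log HRs are pooled by inverse variance, with the DL
random-effects variant as the headline number.

## Co-expression and enrichment

Correlation with the target gene is computed across all samples of a
cohort (tumor and normal together — group separation itself contributes
signal, as in the real workflow), Pearson by default with exact-t
p-values, Spearman selectable; BH adjustment is per cohort across genes.
Vote counting then selects genes significant (adj. p < 0.05) with
consistent sign in at least 7 cohorts (positive) or 5 cohorts (negative),
intersected with the CI-sign DEG lists; "more than six/four" is read
strictly as ≥7/≥5, and both thresholds are configurable. Votes are
counted over the individual datasets, not merged platform units, because
the thresholds are calibrated to a dataset count. Enrichment is the
upper-tail hypergeometric over-representation test with BH across sets,
all quantities restricted to the supplied universe.

## Clinical statistics

2^−ΔΔCt relative quantification uses ΔCt = Ct_target − Ct_reference per
condition and ΔΔCt = ΔCt_case − ΔCt_ctrl; the fold change is invariant to
adding a constant to all four Ct values. Paired comparisons select the
test from a median-centered Levene homogeneity check at 0.05 (homogeneous
→ paired t, else Wilcoxon signed-rank); degenerate all-zero differences
report p = 1, constant nonzero differences report p = 0 (t → ∞). Grouped
comparisons select by per-group Shapiro–Wilk at 0.05 between Student
t/ANOVA and Mann–Whitney/Kruskal–Wallis. All tests are two-sided and each
decision is logged.

IHC staining scores 0–3 collapse to negative (0–1) / positive (2–3).
Contingency association uses the Pearson chi-square **without continuity
correction** — the convention that reproduces printed clinical 2×2 tables
(e.g. p = 0.022, 0.007, 0.017, 0.920 for the worked nodal-stage/PNI
examples in the tests); Yates correction is available behind a flag.
Pairwise p-values for multi-level variables are reported unadjusted, as
clinical tables conventionally print them, with BH available separately.
Rates are rounded half-up to 2 decimals.

## Immune fractions

Deconvolved fractions (22 CIBERSORT LM22-style cell types by default) are
an input contract; the ν-SVR deconvolution itself is out of scope.
Samples split at the median marker expression (ties low); each cell type
is compared by a two-sided t-test — Welch by default, pooled-variance
(`equal_var=True`) for strict replication of a Student-t convention; the
difference between the two is logged by the caller's choice. The primary
output flags raw p < 0.05 (matching the convention of reporting only
significant rows); a BH column is supplementary. Fractions are
compositional, so shifting one component's concentration perturbs all
others — a true single-component shift typically flags several cell
types, as the generator's tests show.

## Mutation screen

"Mutation frequency" is the fraction of roster samples carrying ≥1 SNV in
the gene — the per-sample collapse is the only definition consistent with
a percent threshold over a fixed sample count. The ≥5% filter is
inclusive (2/36 = 5.6% passes, 1/36 does not). An optional user-supplied
cancer-gene list replaces any database lookup; without it all SNVs are
retained. Coordinates are 1-based as in VCF; multi-allelic records split
per alternate allele; gene assignment must be present in the input.

## Synthetic-data generator

The expression model per gene g and sample j is

    x_gj = μ_g + batch_shift + δ_g·sd_g·1[tumor] + λ_g·f_j·σ + ε_gj

with f_j a standard-normal latent factor shared by the target and its
co-expression block, ε ~ N(0, σ²), and sd_g = σ√(1+λ_g²) the gene's total
SD. Scaling the group shift by sd_g makes δ_g the gene's **true
standardized mean difference exactly**, including for factor-loaded
genes — the generator's defining convention, required for parameter
recovery to be well-posed. Baselines μ_g ~ N(8, 2) are shared across
cohorts; per-cohort seeds are split from the root seed by hashing the
dataset id, so adding a cohort never perturbs the others. The block
splits into a positive half (λ, δ = +0.8) and a negative half (−λ,
δ = −0.8), plus 10% unloaded DEG-only genes, so DEG status and
co-expression status can disagree.

The **default profile** — the study conditions used by the recovery
suites — is 18 cohorts over 6 platforms, 30 tumor / 30 normal each, 400
genes, target δ = 0.9, a 60-gene block at loading 0.8, σ = 1, alternating
batch shifts. These sizes keep the full suite and the acceptance script
in the tens of seconds while giving a pooled SE of ≈0.065 for the target
SMD, so recovery bands are meaningful. Survival uses exponential event
times with hazard baseline·exp(β·z) on standardized expression z, and
uniform (0, T_max) censoring with T_max solved numerically (quantile-grid
expectation + Brent root find) to hit the requested censoring fraction in
expectation. Because the median split dichotomizes a continuous hazard
gradient, the group-level log HR is a functional of the whole design, not
β itself; recovery tests therefore compare the pooled estimate against a
large-sample (n = 20 000) evaluation of the same functional. Immune
fractions are Dirichlet per group; clinical tables are Bernoulli per
stratum; variant tables are Bernoulli per gene × sample with deterministic
unique positions.

What the generator does **not** emulate: probe-level microarray artifacts,
heavy-tailed or count noise (RNA-seq overdispersion), correlated gene
blocks beyond the single shared factor, non-proportional hazards, or
compositional immune signatures estimated with error. Passing recovery
tests therefore demonstrates correctness of the estimators under the
stated models, not robustness to real-data pathologies.

## Numerical choices

- Normal 97.5% quantile 1.959963984540054 everywhere a 95% CI is formed.
- Continuity correction 0.5 applied to all four cells of a study only
  when that study has a zero cell (diagnostics); logit/log-scale CIs by
  the delta method.
- Perfect correlations map to the smallest positive double rather than
  p = 0.
- Youden ties resolved toward the lower threshold (higher sensitivity);
  median ties to the low group; ranking ties in the mutation screen
  broken lexicographically.
- SROC optimizer: Nelder–Mead, 4000 iterations, Cholesky-parameterized
  covariance bounded away from singularity; mean standard errors from a
  numerical Hessian in the mean parameters.
- TSV outputs print floats at 6 significant digits; manifests record
  SHA-256 checksums of every output.

## Known limitations

- The log-rank HR estimator is biased toward the null under strong
  non-proportionality; a Cox estimator is intentionally out of scope.
- The bivariate SROC ML fit can be fragile for k ≲ 5 heterogeneous
  studies; the univariate fallback is flagged but less efficient.
- Gene identifiers are matched as exact strings; no alias resolution.
- The vote-count thresholds (≥7/≥5) presume a compendium of roughly 18
  datasets; with many fewer datasets the positive rule is unsatisfiable
  and the package warns rather than rescaling silently.
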
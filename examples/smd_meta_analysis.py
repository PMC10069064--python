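"""Pool a target gene's standardized mean difference across 18 cohorts.

Simulates the default multi-platform profile (true SMD 0.9 for the target
gene), computes Hedges g per cohort, pools by DerSimonian–Laird, and
prints the forest table.
"""

from oscmeta import default_profile, forest_table, gen_expression_cohorts, hedges_g, pool_dl

datasets, truth = gen_expression_cohorts(default_profile(seed=1))
records = [
    hedges_g(ds.values(truth.target_gene, "tumor"),
             ds.values(truth.target_gene, "normal"), ds.dataset_id)
    for ds in datasets
]
pooled = pool_dl(records)

print(forest_table(records, pooled).to_string(index=False, float_format="%.3f"))
print(
    f"\nPooled SMD = {pooled.pooled_g:.3f} "
    f"[{pooled.ci_low:.3f}, {pooled.ci_high:.3f}], "
    f"tau2 = {pooled.tau2:.4f}, I2 = {100 * pooled.I2:.0f}%"
)
print("A pooled CI excluding 0 calls the gene differentially expressed;")
print(f"the generator planted a true standardized difference of 0.9.")
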
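"""Determinism and construction guarantees of the synthetic generators."""

import numpy as np
import pandas as pd
import pytest

from oscmeta.effects import hedges_g
from oscmeta.simulate import (
    CohortSpec,
    gen_clinical_table,
    gen_expression_cohorts,
    gen_immune_fractions,
    gen_survival_cohort,
    gen_variant_table,
    split_seed,
)


def _spec(**kw):
    base = dict(
        dataset_id="D1", platform_id="P1", n_tumor=20, n_normal=20,
        n_genes=60, target_effect=0.0, block_genes=10, block_loading=0.5,
        seed=3,
    )
    base.update(kw)
    return CohortSpec(**base)


class TestExpressionGenerator:
    def test_deterministic_given_seed(self):
        a, _ = gen_expression_cohorts([_spec()])
        b, _ = gen_expression_cohorts([_spec()])
        assert (a[0].matrix == b[0].matrix).all()

    def test_adding_cohort_does_not_perturb_existing(self):
        solo, _ = gen_expression_cohorts([_spec()])
        both, _ = gen_expression_cohorts([_spec(), _spec(dataset_id="D2")])
        assert (solo[0].matrix == both[0].matrix).all()

    def test_null_effect_gives_null_g(self):
        gs = []
        for seed in range(30):
            ds, truth = gen_expression_cohorts(
                [_spec(seed=seed, target_effect=0.0, block_loading=0.0)]
            )
            rec = hedges_g(ds[0].values(truth.target_gene, "tumor"),
                           ds[0].values(truth.target_gene, "normal"))
            gs.append(rec.g)
        se = np.sqrt(40 / 400)  # large-sample SE of g at n=20/20
        assert abs(np.mean(gs)) < 3 * se / np.sqrt(30)

    def test_true_smd_realized_for_loaded_target(self):
        """The group shift is scaled by the gene's total SD, so the
        realized standardized difference equals target_effect even when
        the target carries a latent-factor loading."""
        gs = []
        for seed in range(40):
            ds, truth = gen_expression_cohorts(
                [_spec(seed=seed, n_tumor=100, n_normal=100,
                       target_effect=1.0, block_loading=0.8)]
            )
            gs.append(hedges_g(ds[0].values(truth.target_gene, "tumor"),
                               ds[0].values(truth.target_gene, "normal")).g)
        assert np.mean(gs) == pytest.approx(1.0, abs=0.08)

    def test_block_genes_correlate_with_target(self):
        ds, truth = gen_expression_cohorts(
            [_spec(block_loading=0.8, n_genes=100, block_genes=50)]
        )
        d = ds[0]
        target = d.values(truth.target_gene)
        block = truth.pos_block | truth.neg_block
        nulls = {g for g, eff in truth.gene_effects.items()
                 if eff == 0 and g != truth.target_gene}
        r_block = np.mean([abs(np.corrcoef(d.values(g), target)[0, 1]) for g in block])
        r_null = np.mean([abs(np.corrcoef(d.values(g), target)[0, 1]) for g in nulls])
        assert r_block > r_null

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            gen_expression_cohorts([_spec(), _spec()])

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            _spec(n_tumor=1)
        with pytest.raises(ValueError):
            _spec(noise_sd=0.0)
        with pytest.raises(ValueError):
            _spec(block_genes=60)

    def test_raw_mode_exponentiates(self):
        log_ds, _ = gen_expression_cohorts([_spec()])
        raw_ds, _ = gen_expression_cohorts([_spec()], as_raw=True)
        assert raw_ds[0].scale == "raw"
        assert np.allclose(raw_ds[0].matrix, 2.0 ** log_ds[0].matrix)


class TestSurvivalGenerator:
    def test_no_censoring_all_events(self):
        t = gen_survival_cohort(50, beta=0.5, censor_rate=0.0, seed=1)
        assert t["event"].sum() == 50

    def test_censor_rate_approximately_achieved(self):
        fracs = [
            1 - gen_survival_cohort(400, beta=0.5, censor_rate=0.3, seed=s)["event"].mean()
            for s in range(10)
        ]
        assert np.mean(fracs) == pytest.approx(0.3, abs=0.03)

    def test_positive_beta_shortens_high_expression_survival(self):
        t = gen_survival_cohort(2000, beta=0.8, seed=2)
        hi = t[t["expression"] > 0]["time"].median()
        lo = t[t["expression"] <= 0]["time"].median()
        assert hi < lo

    def test_bad_censor_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_survival_cohort(50, beta=0.0, censor_rate=1.0)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            gen_survival_cohort(5, beta=0.0)


class TestImmuneGenerator:
    def test_rows_on_simplex(self):
        df = gen_immune_fractions(30, seed=4)
        vals = df.drop(columns=["sample_id", "expression", "true_group"]).to_numpy()
        assert np.allclose(vals.sum(axis=1), 1.0, atol=1e-9)

    def test_median_split_recovers_groups(self):
        df = gen_immune_fractions(25, seed=4)
        med = df["expression"].median()
        assert ((df["expression"] > med) == (df["true_group"] == "high")).all()

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            gen_immune_fractions(10, celltypes=["a", "b"], alpha_low=[1.0, 0.0],
                                 alpha_high=[1.0, 1.0])


class TestVariantGenerator:
    def test_prob_zero_empty(self):
        assert len(gen_variant_table(36, {"G1": 0.0})) == 0

    def test_prob_one_full(self):
        t = gen_variant_table(36, {"G1": 1.0})
        assert t["sample_id"].nunique() == 36

    def test_frequency_within_binomial_bounds(self):
        # 99% central interval for Binomial(36, 0.2): [2, 12]
        t = gen_variant_table(36, {"G1": 0.2}, seed=6)
        assert 2 <= t["sample_id"].nunique() <= 12

    def test_records_unique(self):
        t = gen_variant_table(20, {"G1": 0.8, "G2": 0.8}, seed=1)
        assert not t.duplicated(subset=["sample_id", "chrom", "pos", "alt"]).any()


class TestClinicalGenerator:
    def test_total_rows(self):
        t = gen_clinical_table({"N0": (23, 0.3), "N1": (37, 0.6)}, seed=1)
        assert len(t) == 60

    def test_complete_separation_detected(self):
        from oscmeta.clinical import chi2_association

        t = gen_clinical_table({"A": (20, 1.0), "B": (20, 0.0)}, seed=1)
        counts = (
            t.groupby("stratum")["positive"]
            .agg(pos="sum", neg=lambda s: (1 - s).sum())
            .to_numpy()
        )
        _, _, p = chi2_association(counts)
        assert p < 1e-6

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            gen_clinical_table({"A": (0, 0.5)})


class TestSeedSplitting:
    def test_labels_give_distinct_streams(self):
        assert split_seed(1, "a") != split_seed(1, "b")
        assert split_seed(1, "a") != split_seed(2, "a")

    def test_below_2_31(self):
        for s in range(50):
            assert 0 <= split_seed(s, f"x{s}") < 2**31
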
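"""BH adjustment, the DE screen, target correlation, vote counting and
hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pytest

from oscmeta.coexpression import (
    CorrelationRecord,
    bh_adjust,
    correlate_target,
    hypergeom_enrich,
    prelim_de_screen,
    vote_count_coexpression,
)
from oscmeta.ingest import GeneSetCollection
from oscmeta.simulate import CohortSpec, gen_expression_cohorts


def brute_bh(p):
    """adj_i = min over ranks j >= rank(i) of p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    rank = {i: pos for pos, i in enumerate(order, start=1)}
    return [
        min(min(p[j] * m / rank[j] for j in order if rank[j] >= rank[i]), 1.0)
        for i in range(m)
    ]


class TestBHAdjust:
    def test_hand_worked_stepup(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.3] * 5), 0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 12))
            p = rng.random(m).tolist()
            assert np.allclose(bh_adjust(p), brute_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(30)
        assert np.all(bh_adjust(p) >= p - 1e-15)


@pytest.fixture()
def loaded_cohort():
    spec = CohortSpec(
        dataset_id="D", platform_id="P", n_tumor=20, n_normal=20,
        n_genes=120, target_effect=1.0, block_genes=30, block_loading=0.8,
        seed=42,
    )
    ds, truth = gen_expression_cohorts([spec])
    return ds[0], truth


class TestPrelimScreen:
    def test_planted_effects_detected(self, loaded_cohort):
        ds, truth = loaded_cohort
        up, down = prelim_de_screen(ds, lfc_min=0.5)
        true_up = {g for g, d in truth.gene_effects.items() if d > 0}
        assert len(up & true_up) / len(true_up) > 0.5
        # null genes rarely selected
        nulls = {g for g, d in truth.gene_effects.items() if d == 0}
        assert len((up | down) & nulls) <= 3

    def test_selection_invariant_to_sample_order(self, loaded_cohort):
        ds, _ = loaded_cohort
        perm = np.random.default_rng(0).permutation(ds.matrix.shape[1])
        from dataclasses import replace

        shuffled = replace(
            ds,
            matrix=ds.matrix[:, perm],
            sample_ids=tuple(ds.sample_ids[i] for i in perm),
            group=ds.group[perm],
        )
        assert prelim_de_screen(ds) == prelim_de_screen(shuffled)

    def test_small_groups_rejected(self, loaded_cohort):
        ds, _ = loaded_cohort
        from dataclasses import replace

        tiny = replace(
            ds,
            matrix=ds.matrix[:, :4],
            sample_ids=ds.sample_ids[:4],
            group=ds.group[:4],
        )
        with pytest.raises(ValueError):
            prelim_de_screen(tiny)


class TestCorrelateTarget:
    def test_target_correlates_perfectly_with_itself(self, loaded_cohort):
        ds, truth = loaded_cohort
        recs = {r.gene: r for r in correlate_target(ds, truth.target_gene)}
        assert recs[truth.target_gene].r == pytest.approx(1.0)
        assert recs[truth.target_gene].p > 0  # smallest positive, not zero

    def test_block_genes_correlate_more_than_nulls(self, loaded_cohort):
        ds, truth = loaded_cohort
        recs = correlate_target(ds, truth.target_gene)
        block = truth.pos_block | truth.neg_block
        nulls = {g for g, d in truth.gene_effects.items() if d == 0}
        r_block = np.mean([abs(r.r) for r in recs if r.gene in block])
        r_null = np.mean([abs(r.r) for r in recs if r.gene in nulls])
        assert r_block > r_null

    def test_exact_anticorrelation(self):
        import pandas as pd

        from oscmeta.ingest import dataset_from_frames

        expr = pd.DataFrame(
            {"s1": [1, -1], "s2": [2, -2], "s3": [3, -3], "s4": [4, -4]},
            index=["A", "B"],
        ).astype(float)
        pheno = pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3", "s4"],
             "group": ["tumor", "tumor", "normal", "normal"]}
        )
        ds = dataset_from_frames(expr, pheno, "X")
        recs = {r.gene: r for r in correlate_target(ds, "A")}
        assert recs["B"].r == pytest.approx(-1.0)
        assert recs["B"].p > 0

    def test_missing_target_rejected(self, loaded_cohort):
        ds, _ = loaded_cohort
        with pytest.raises(KeyError):
            correlate_target(ds, "NOPE")


def _corr(gene, ds, r, adj_p):
    return CorrelationRecord(gene, ds, r, adj_p, adj_p)


class TestVoteCount:
    def _votes(self, gene, n_sig, n_total, r=0.5):
        return {
            f"d{i}": [_corr(gene, f"d{i}", r, 0.01 if i < n_sig else 0.5)]
            for i in range(n_total)
        }

    def test_seven_of_eighteen_with_deg_selected(self):
        pos, neg = vote_count_coexpression(
            self._votes("G1", 7, 18), {"G1"}, set()
        )
        assert pos == {"G1"}

    def test_six_votes_insufficient(self):
        pos, _ = vote_count_coexpression(self._votes("G1", 6, 18), {"G1"}, set())
        assert pos == set()

    def test_non_deg_excluded_despite_votes(self):
        pos, neg = vote_count_coexpression(self._votes("G1", 10, 18), set(), set())
        assert pos == set() and neg == set()

    def test_negative_branch_threshold_five(self):
        corr = self._votes("G2", 5, 18, r=-0.5)
        _, neg = vote_count_coexpression(corr, set(), {"G2"})
        assert neg == {"G2"}

    def test_monotone_in_thresholds(self):
        corr = self._votes("G1", 9, 18)
        loose, _ = vote_count_coexpression(corr, {"G1"}, set(), up_min_datasets=5)
        tight, _ = vote_count_coexpression(corr, {"G1"}, set(), up_min_datasets=10)
        assert tight <= loose

    def test_thresholds_beyond_datasets_warn_empty(self):
        with pytest.warns(UserWarning):
            pos, neg = vote_count_coexpression(
                self._votes("G1", 2, 3), {"G1"}, set(),
                up_min_datasets=5, down_min_datasets=5,
            )
        assert pos == set() and neg == set()


class TestHypergeomEnrich:
    def _sets(self, **kw):
        return GeneSetCollection({k: ("", tuple(v)) for k, v in kw.items()})

    def test_full_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        sets = self._sets(S=universe[:5])
        res = hypergeom_enrich(universe[:5], sets, universe)
        assert res[0].p == pytest.approx(1 / math.comb(20, 5), rel=1e-9)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        sets = self._sets(S=universe[:5])
        res = hypergeom_enrich(universe[10:15], sets, universe)
        assert res[0].p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        # P(overlap >= k) by enumerating all C(N, n) draws, N <= 12
        for _ in range(25):
            N = int(rng.integers(5, 13))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            members = list(rng.choice(universe, size=K, replace=False))
            selected = list(rng.choice(universe, size=n, replace=False))
            k_obs = len(set(members) & set(selected))
            total = hits = 0
            for draw in itertools.combinations(universe, n):
                total += 1
                if len(set(draw) & set(members)) >= k_obs:
                    hits += 1
            res = hypergeom_enrich(selected, self._sets(S=members), universe)
            assert res[0].p == pytest.approx(hits / total, rel=1e-9)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrich(["a"], self._sets(S=["a"]), [])
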
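"""Readers, scaling, quantile normalization and platform merging."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from oscmeta.ingest import (
    ExpressionDataset,
    auto_log,
    dataset_from_frames,
    log_scale,
    merge_platform,
    quantile_normalize,
    read_expression_table,
    read_gmt,
    write_expression_table,
)


def _ds(matrix, scale="log", dsid="D1", platform="P1", groups=None):
    matrix = np.asarray(matrix, dtype=float)
    ng, ns = matrix.shape
    if groups is None:
        groups = ["tumor"] * (ns // 2) + ["normal"] * (ns - ns // 2)
    return ExpressionDataset(
        dataset_id=dsid, platform_id=platform, matrix=matrix,
        gene_ids=tuple(f"g{i}" for i in range(ng)),
        sample_ids=tuple(f"{dsid}_s{j}" for j in range(ns)),
        group=np.array(groups, dtype=object), scale=scale,
    )


class TestReadWrite:
    def test_round_trip_bit_identical(self, tmp_path):
        ds = _ds([[1.5, 2.25, 3.125], [4.0, 5.5, 6.75], [0.5, 0.25, 0.125]])
        path = tmp_path / "m.tsv"
        write_expression_table(ds, path)
        df = read_expression_table(path)
        assert (df.to_numpy() == ds.matrix).all()
        assert list(df.index) == list(ds.gene_ids)

    def test_duplicate_gene_rejected_by_name(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\ts1\ts2\nGENE1\t1\t2\nGENE1\t3\t4\n")
        with pytest.raises(ValueError, match="GENE1"):
            read_expression_table(path)

    def test_comma_delimiter_sniffed(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("gene,s1,s2\ng1,1.5,2.5\ng2,3.5,4.5\n")
        df = read_expression_table(path)
        assert df.shape == (2, 2)
        assert df.loc["g2", "s2"] == 4.5

    def test_non_numeric_cell_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\ts1\ts2\ng1\t1\toops\n")
        with pytest.raises(ValueError, match="s2"):
            read_expression_table(path)

    def test_samples_rows_orientation(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("sample\tg1\tg2\ns1\t1\t2\ns2\t3\t4\n")
        df = read_expression_table(path, orientation="samples-rows")
        assert list(df.index) == ["g1", "g2"]


class TestScaling:
    def test_log_of_zero_is_log2_pseudocount(self):
        ds = _ds([[0.0, 1023.999]], scale="raw", groups=["tumor", "normal"])
        out = log_scale(ds)
        assert out.matrix[0, 0] == pytest.approx(-9.9658, abs=1e-4)
        assert out.matrix[0, 1] == pytest.approx(10.0, abs=1e-4)
        assert out.scale == "log"

    def test_double_log_rejected(self):
        ds = _ds([[1.0, 2.0]], scale="log", groups=["tumor", "normal"])
        with pytest.raises(ValueError):
            log_scale(ds)

    def test_negative_raw_rejected(self):
        ds = _ds([[-1.0, 2.0]], scale="raw", groups=["tumor", "normal"])
        with pytest.raises(ValueError):
            log_scale(ds)

    def test_auto_log_leaves_log_like_data(self):
        ds = _ds(np.full((5, 4), 7.0) + np.eye(5, 4), scale="raw")
        out = auto_log(ds)
        assert (out.matrix == ds.matrix).all()
        assert out.scale == "log"  # relabelled, not transformed

    def test_auto_log_transforms_large_values(self):
        ds = _ds(np.full((5, 4), 10000.0), scale="raw")
        out = auto_log(ds)
        assert out.matrix.max() < 20

    def test_auto_log_idempotent(self):
        ds = _ds(np.random.default_rng(0).uniform(0, 10000, (20, 6)), scale="raw")
        once = auto_log(ds)
        twice = auto_log(once)
        assert (once.matrix == twice.matrix).all()


class TestQuantileNormalize:
    def test_identical_samples_unchanged(self):
        ds = _ds([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]], groups=["tumor", "normal"])
        out = quantile_normalize(ds)
        assert np.allclose(out.matrix, ds.matrix)

    def test_rank_mean_oracle(self):
        ds = _ds([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]], groups=["tumor", "normal"])
        out = quantile_normalize(ds)
        assert np.allclose(out.matrix[:, 0], [2.5, 3.5, 4.5])
        assert np.allclose(out.matrix[:, 1], [2.5, 3.5, 4.5])

    def test_columns_share_value_multiset(self, rng):
        ds = _ds(rng.normal(8, 2, (30, 6)))
        out = quantile_normalize(ds)
        ref = np.sort(out.matrix[:, 0])
        for j in range(1, 6):
            assert np.allclose(np.sort(out.matrix[:, j]), ref)

    def test_idempotent(self, rng):
        ds = _ds(rng.normal(8, 2, (30, 6)))
        once = quantile_normalize(ds)
        assert np.allclose(quantile_normalize(once).matrix, once.matrix)

    def test_sample_permutation_equivariant(self, rng):
        ds = _ds(rng.normal(8, 2, (30, 6)))
        out = quantile_normalize(ds).matrix
        perm = rng.permutation(6)
        shuffled = replace(
            ds, matrix=ds.matrix[:, perm],
            sample_ids=tuple(ds.sample_ids[i] for i in perm), group=ds.group[perm],
        )
        assert np.allclose(quantile_normalize(shuffled).matrix, out[:, perm])

    def test_constant_sample_warns(self, rng):
        mat = rng.normal(8, 2, (10, 3))
        mat[:, 1] = 5.0
        with pytest.warns(UserWarning):
            quantile_normalize(_ds(mat, groups=["tumor", "normal", "normal"]))


class TestMergePlatform:
    def test_self_merge_halves_identical(self, rng):
        mat = rng.normal(8, 2, (10, 6))
        a = _ds(mat, dsid="A")
        b = _ds(mat, dsid="B")
        merged = merge_platform([a, b])
        assert np.allclose(merged.matrix[:, :6], merged.matrix[:, 6:])

    def test_opposite_batch_shifts_removed(self, rng):
        base = rng.normal(8, 2, (10, 8))
        a = _ds(base + 2.0, dsid="A")
        b = _ds(base - 2.0, dsid="B")
        merged = merge_platform([a, b])
        mean_a = merged.matrix[:, np.array(merged.batch) == "A"].mean(axis=1)
        mean_b = merged.matrix[:, np.array(merged.batch) == "B"].mean(axis=1)
        assert np.allclose(mean_a, mean_b)

    def test_within_batch_variance_preserved(self, rng):
        a = _ds(rng.normal(8, 2, (10, 6)), dsid="A")
        b = _ds(rng.normal(5, 1, (10, 6)), dsid="B")
        merged = merge_platform([a, b])
        var_a = merged.matrix[:, np.array(merged.batch) == "A"].var(axis=1)
        # gene order changes to sorted shared genes; map back
        idx = [a.gene_index[g] for g in merged.gene_ids]
        assert np.allclose(var_a, a.matrix[idx].var(axis=1))

    def test_group_labels_preserved(self, rng):
        a = _ds(rng.normal(size=(4, 6)), dsid="A")
        b = _ds(rng.normal(size=(4, 6)), dsid="B")
        merged = merge_platform([a, b])
        assert list(merged.group) == list(a.group) + list(b.group)

    def test_empty_intersection_reports_counts(self, rng):
        a = _ds(rng.normal(size=(3, 4)), dsid="A")
        b = replace(_ds(rng.normal(size=(3, 4)), dsid="B"),
                    gene_ids=("x1", "x2", "x3"))
        with pytest.raises(ValueError, match="gene counts"):
            merge_platform([a, b])

    def test_cross_platform_merge_rejected(self, rng):
        a = _ds(rng.normal(size=(3, 4)), dsid="A", platform="P1")
        b = _ds(rng.normal(size=(3, 4)), dsid="B", platform="P2")
        with pytest.raises(ValueError):
            merge_platform([a, b])


class TestGmt:
    def test_basic_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tA\tB\n")
        gs = read_gmt(p)
        assert gs.members("S1") == ("A", "B")

    def test_duplicate_member_warns_and_dedups(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tA\tA\n")
        with pytest.warns(UserWarning):
            gs = read_gmt(p)
        assert gs.members("S1") == ("A",)

    def test_short_line_reports_number(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tA\nS2\tonly\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(p)

    def test_empty_file_ok(self, tmp_path):
        p = tmp_path / "e.gmt"
        p.write_text("")
        assert len(read_gmt(p)) == 0


class TestInclusionRule:
    def test_minimum_three_per_group(self, rng):
        ds = _ds(rng.normal(size=(5, 5)),
                 groups=["tumor", "tumor", "normal", "normal", "normal"])
        with pytest.raises(ValueError, match="3"):
            ds.check_inclusion()

    def test_phenotype_attachment(self):
        expr = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g1"])
        pheno = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "group": ["tumor", "normal"]}
        )
        ds = dataset_from_frames(expr, pheno, "D")
        assert ds.n_tumor == 1 and ds.n_normal == 1
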
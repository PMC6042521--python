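"""Evaluation machinery: fold-change model, metrics, stratification, DE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import titrabench as tb
from titrabench.evaluate import (
    DETECTION_TPM_THRESHOLD,
    cpm,
    de_test_table,
    gene_lengths,
    gene_tpm,
    normalize_counts,
    size_factors,
    trna_cumulative_error,
)
from titrabench.tables import AbundanceTable
from conftest import make_transcript


def wide(data, ids):
    df = pd.DataFrame(data, index=ids)
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df


class TestDetect:
    @pytest.mark.parametrize("tpm,expected", [(0.2, True), (0.1, False), (0.0, False),
                                              (0.1000001, True)])
    def test_strict_threshold(self, tpm, expected):
        assert tb.detect(tpm) is expected

    def test_vectorized(self):
        out = tb.detect(np.array([0.0, 0.1, 0.2]))
        assert out.tolist() == [False, False, True]
        assert DETECTION_TPM_THRESHOLD == 0.1


class TestExpectedCdLog2fc:
    @pytest.mark.parametrize("z", [0.5, 1.0, 1.43, 3.0])
    def test_unchanged_genes_predict_zero(self, z):
        assert tb.expected_cd_log2fc(0.0, z) == pytest.approx(0.0, abs=1e-12)

    def test_frozen_evaluations_at_z_143(self):
        # independent evaluation: k1 = 4.29/5.29, k2 = 1.43/4.43
        k1, k2 = 4.29 / 5.29, 1.43 / 4.43
        for lab in (2.0, -2.0):
            r = 2.0 ** lab
            expected = np.log2(k1 * r + 1 - k1) - np.log2(k2 * r + 1 - k2)
            assert tb.expected_cd_log2fc(lab, 1.43) == pytest.approx(expected, abs=1e-12)
        assert tb.expected_cd_log2fc(2.0, 1.43) == pytest.approx(0.8026, abs=5e-4)
        assert tb.expected_cd_log2fc(-2.0, 1.43) == pytest.approx(-0.952, abs=1e-3)

    def test_monotone_in_fold_change(self):
        x = np.linspace(-6, 6, 200)
        y = tb.expected_cd_log2fc(x, 1.43)
        assert np.all(np.diff(y) > 0)

    def test_nonfinite_propagates_with_warning(self):
        with pytest.warns(UserWarning):
            out = tb.expected_cd_log2fc(np.array([0.0, np.nan]), 1.43)
        assert np.isnan(out[1])

    def test_invalid_z(self):
        with pytest.raises(ValueError):
            tb.expected_cd_log2fc(0.0, -1.0)


class TestRSquared:
    def test_perfect_fit(self):
        assert tb.r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_hand_worked_half(self):
        assert tb.r_squared([1, 2, 3], [1, 2, 4]) == pytest.approx(0.5)

    def test_negative_r2_semantics(self):
        # 1 - (81 + 64 + 49)/2 = -96: far worse than the mean predictor
        assert tb.r_squared([1, 2, 3], [10, 10, 10]) == pytest.approx(-96.0)

    def test_constant_measurements_rejected(self):
        with pytest.raises(ValueError):
            tb.r_squared([2, 2, 2], [1, 2, 3])

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_matches_naive_reimplementation(self, data):
        n = data.draw(st.integers(2, 20))
        y = data.draw(st.lists(st.floats(-10, 10), min_size=n, max_size=n))
        f = data.draw(st.lists(st.floats(-10, 10), min_size=n, max_size=n))
        y, f = np.array(y), np.array(f)
        if np.var(y) == 0:
            return
        ybar = sum(y) / len(y)
        naive = 1 - sum((yi - fi) ** 2 for yi, fi in zip(y, f)) / sum(
            (yi - ybar) ** 2 for yi in y
        )
        assert tb.r_squared(y, f) == pytest.approx(naive, rel=1e-9, abs=1e-9)
        # shifting both vectors by a constant leaves R² unchanged
        assert tb.r_squared(y + 3.0, f + 3.0) == pytest.approx(
            tb.r_squared(y, f), rel=1e-6, abs=1e-6
        )


class TestRmse:
    @pytest.mark.parametrize(
        "y,f,expected",
        [([1, 2], [1, 2], 0.0), ([0, 0], [1, 1], 1.0), ([1, 2], [2, 4], np.sqrt(2.5))],
    )
    def test_hand_worked(self, y, f, expected):
        assert tb.rmse(y, f) == pytest.approx(expected)

    def test_symmetry_and_empty(self):
        y, f = np.array([1.0, 5.0, -2.0]), np.array([0.0, 4.0, 4.0])
        assert tb.rmse(y, f) == tb.rmse(f, y)
        with pytest.raises(ValueError):
            tb.rmse([], [])


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = tb.roc_auc([0.001, 0.002, 0.5, 0.9], [True, True, False, False])
        assert auc == 1.0

    def test_all_tied_is_half(self):
        _, auc = tb.roc_auc([0.2, 0.2, 0.2], [True, True, False])
        assert auc == 0.5

    def test_hand_worked_pair_counting(self):
        # 1 of 2 (DE, null) pairs correctly ordered
        _, auc = tb.roc_auc([0.01, 0.2, 0.05], [True, True, False])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            tb.roc_auc([0.1, 0.2], [True, True])

    def test_inverted_pvalues_flip_auc(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        truth = rng.random(40) < 0.5
        if truth.all() or not truth.any():
            truth[0] = ~truth[0]
        _, auc = tb.roc_auc(p, truth)
        _, auc_inv = tb.roc_auc(1 - p, truth)
        assert auc_inv == pytest.approx(1 - auc, abs=1e-12)


class TestDeTest:
    def test_identical_replicates_null(self):
        fc, p = tb.de_test([10, 10, 10], [10, 10, 10])
        assert (fc, p) == (0.0, 1.0)

    def test_hand_worked_fold_change(self):
        # CPM means 400 vs 100, negligible variance: log2(400.5/100.5) = 1.995
        fc, p = tb.de_test([400.0, 400.0001, 399.9999], [100.0, 100.0001, 99.9999])
        assert fc == pytest.approx(np.log2(400.5 / 100.5), abs=1e-4)
        assert fc == pytest.approx(1.995, abs=1e-3)
        assert p < 1e-6

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            tb.de_test([1.0], [2.0, 3.0])

    def test_table_version_matches_scalar(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(
            rng.poisson(100, size=(20, 6)).astype(float),
            index=[f"G{i}" for i in range(20)],
            columns=pd.MultiIndex.from_tuples(
                [("A", 1), ("A", 2), ("A", 3), ("B", 1), ("B", 2), ("B", 3)]
            ),
        )
        table = de_test_table(vals, "A", "B")
        for g in vals.index[:5]:
            fc, p = tb.de_test(vals.loc[g, "A"], vals.loc[g, "B"])
            assert table.loc[g, "log2fc"] == pytest.approx(fc)
            assert table.loc[g, "p_value"] == pytest.approx(p)


class TestNormalization:
    def test_cpm_columns_sum_to_million(self):
        vals = wide({("A", 1): [10.0, 30.0], ("B", 1): [5.0, 5.0]}, ["G1", "G2"])
        out = cpm(vals)
        assert np.allclose(out.sum(axis=0), 1e6)

    def test_size_factors_recover_scaling(self):
        rng = np.random.default_rng(9)
        base = rng.lognormal(3, 1, size=50)
        vals = wide(
            {("A", 1): base * 2.0, ("A", 2): base * 0.5, ("B", 1): base},
            [f"G{i}" for i in range(50)],
        )
        sf = size_factors(vals)
        ratios = sf / sf.iloc[2]
        assert ratios.iloc[0] == pytest.approx(2.0, rel=1e-9)
        assert ratios.iloc[1] == pytest.approx(0.5, rel=1e-9)

    def test_median_of_ratios_removes_composition_shift(self):
        rng = np.random.default_rng(10)
        base = rng.lognormal(3, 1, size=101)
        vals = wide(
            {("A", 1): base * 3.0, ("B", 1): base}, [f"G{i}" for i in range(101)]
        )
        norm = normalize_counts(vals, "median_of_ratios")
        assert np.allclose(norm[("A", 1)], norm[("B", 1)], rtol=1e-9)
        with pytest.raises(ValueError):
            normalize_counts(vals, "upper_quartile")


class TestStratify:
    def make_table(self, n):
        rng = np.random.default_rng(11)
        return pd.DataFrame(
            {
                "mean_expression": rng.lognormal(2, 2, n),
                "gene_length": rng.integers(60, 5000, n).astype(float),
                "gene_type": rng.choice(["protein_coding", "tRNA", "ERCC"], n),
            },
            index=pd.Index([f"G{i:03d}" for i in range(n)], name="gene_id"),
        )

    def test_expression_scheme_sizes(self):
        table = self.make_table(100)
        strata = tb.stratify(table, "mean_expression")
        sizes = {name: len(idx) for name, idx in strata.items()}
        assert sizes == {"Total RNA": 100, "Top 1%": 1, "Top 10%": 10,
                         "Top 25%": 25, "Bottom 75%": 75}
        top25 = set(strata["Top 25%"])
        assert set(strata["Top 1%"]) <= set(strata["Top 10%"]) <= top25
        assert not top25 & set(strata["Bottom 75%"])

    def test_length_quartiles_partition(self):
        table = self.make_table(8)
        strata = tb.stratify(table, "gene_length")
        assert [len(v) for v in strata.values()] == [2, 2, 2, 2]
        union = set().union(*[set(v) for v in strata.values()])
        assert union == set(table.index)

    def test_gene_type_uses_printed_category_names(self):
        table = self.make_table(30)
        strata = tb.stratify(table, "gene_type")
        assert set(strata) <= {"Protein coding", "tRNA", "ERCC", "rRNA",
                               "Other sncRNA", "Other ncRNA"}

    def test_unknown_scheme_rejected(self):
        with pytest.raises((KeyError, ValueError)):
            tb.stratify(self.make_table(10), "gc_content")


class TestGeneAggregation:
    def make_transcripts(self):
        return [
            make_transcript("G1.T1", "G1", seed=1, length=1049),
            make_transcript("G1.T2", "G1", seed=2, length=1049),
            make_transcript("G2.T1", "G2", seed=3, length=1049),
        ]

    def test_equal_length_isoforms_sum(self):
        transcripts = self.make_transcripts()
        df = wide({("A", 1): [100.0, 300.0, 600.0]}, ["G1.T1", "G1.T2", "G2.T1"])
        df = df / df.sum() * 1e6
        tpm = AbundanceTable(df, unit="TPM")
        out = tb.aggregate_to_gene(tpm, transcripts, library_sizes=1000.0)
        # gene signal proportional to 400 vs 600
        assert out.column("A")["G1"] == pytest.approx(400.0)
        assert out.column("A")["G2"] == pytest.approx(600.0)
        assert out.column("A").sum() == pytest.approx(1000.0)

    def test_single_transcript_genes_preserve_rank(self, default_transcripts, true_tpm):
        out = tb.aggregate_to_gene(true_tpm, default_transcripts)
        gtpm = gene_tpm(true_tpm, default_transcripts)
        single = [
            t.gene_id for t in default_transcripts
            if not t.is_decoy and t.gene_id.startswith(("ERCC", "SNORD"))
        ]
        a = out.column("A")[single].rank()
        b = gtpm.column("A")[single].rank()
        # length-scaling reweights, but within ERCC-like genes of similar
        # length ranks are strongly preserved
        assert (a - b).abs().mean() < len(single) * 0.2

    def test_unknown_transcript_rejected(self, default_transcripts, true_tpm):
        bad = true_tpm.values.copy()
        bad.index = ["X" + str(i) for i in range(len(bad))]
        table = AbundanceTable(bad, unit="TPM")
        with pytest.raises(KeyError):
            tb.aggregate_to_gene(table, default_transcripts)

    def test_gene_length_is_longest_transcript(self):
        transcripts = [
            make_transcript("G1.T1", "G1", seed=1, length=500),
            make_transcript("G1.T2", "G1", seed=2, length=900),
        ]
        assert gene_lengths(transcripts)["G1"] == 900


class TestFoldChangeTable:
    def test_all_zero_genes_excluded_and_logged(self, default_transcripts):
        genes = sorted({t.gene_id for t in default_transcripts if not t.is_decoy})
        rng = np.random.default_rng(13)
        cols = [(s, r) for s in "ABCD" for r in (1, 2)]
        vals = pd.DataFrame(
            rng.poisson(50, size=(len(genes), 8)).astype(float),
            index=pd.Index(genes, name="gene_id"),
            columns=pd.MultiIndex.from_tuples(cols),
        )
        vals.iloc[0] = 0.0
        gv = AbundanceTable(vals, unit="count_scale", level="gene")
        gt = AbundanceTable(vals.div(vals.sum()) * 1e6, unit="TPM", level="gene")
        fc = tb.build_fold_change_table(gv, gt, default_transcripts, z=1.43)
        assert genes[0] in fc.attrs["excluded_genes"]
        assert genes[0] not in fc.index
        assert {"measured_log2fc_AB", "expected_log2fc_CD", "p_value_AB"} <= set(fc.columns)

    def test_trna_cumulative_error_monotone(self, default_transcripts):
        genes = sorted({t.gene_id for t in default_transcripts if not t.is_decoy})
        rng = np.random.default_rng(14)
        cols = [(s, r) for s in "ABCD" for r in (1, 2)]
        vals = pd.DataFrame(
            rng.poisson(50, size=(len(genes), 8)).astype(float) + 1,
            index=pd.Index(genes, name="gene_id"),
            columns=pd.MultiIndex.from_tuples(cols),
        )
        gv = AbundanceTable(vals, unit="count_scale", level="gene")
        gt = AbundanceTable(vals.div(vals.sum()) * 1e6, unit="TPM", level="gene")
        fc = tb.build_fold_change_table(gv, gt, default_transcripts, z=1.43)
        curve = trna_cumulative_error(fc)
        assert len(curve) == 20
        assert curve["cumulative_error"].is_monotonic_increasing
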
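"""Spectral-count ingestion, normalization stages, FDR and Hi3 quantitation."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paxms.identifications import (
    AbundanceEstimate,
    CountMatrix,
    IdentificationRecord,
    absolute_quantity,
    abundance_rank,
    build_matrix,
    compute_fdr,
    hi3_quantify,
    mean_across_replicates,
    percent_of_total,
    quantitative_values,
    read_identifications,
    top_n_membership,
)
from conftest import random_count_matrix


def tsv(text: str):
    return io.StringIO(text)


class TestReader:
    HEADER = "protein\tbait_id\treplicate\tspectral_count\tunique_peptides\tdecoy\n"

    def test_typed_record(self):
        recs = read_identifications(tsv(self.HEADER + "Homer1\tmGluR5\t1\t7\t3\tfalse\n"))
        assert recs == [IdentificationRecord("Homer1", "mGluR5", 1, 7, 3, False)]

    def test_decoy_prefix_without_column(self):
        recs = read_identifications(
            tsv("protein\tbait_id\treplicate\tspectral_count\nREV_Q9QWW1\tSOS1\t1\t2\n")
        )
        assert recs[0].decoy

    def test_header_only_is_empty(self):
        assert read_identifications(tsv(self.HEADER)) == []

    def test_missing_column_is_schema_error(self):
        with pytest.raises(ValueError, match="missing required columns"):
            read_identifications(tsv("protein\tbait_id\treplicate\nA\tb\t1\n"))

    def test_malformed_rows_warn_with_line_numbers(self):
        body = "A\tb\t1\t5\t2\tfalse\nB\tb\tnot_an_int\t5\t2\tfalse\n"
        with pytest.warns(UserWarning, match=r"line\(s\) \[3\]"):
            recs = read_identifications(tsv(self.HEADER + body))
        assert [r.protein for r in recs] == ["A"]

    def test_count_peptide_consistency_enforced(self):
        with pytest.raises(ValueError):
            IdentificationRecord("A", "b", 1, 2, unique_peptides=5)


class TestBuildMatrix:
    def test_missing_cells_are_zero(self):
        recs = [
            IdentificationRecord("p1", "A", 1, 3),
            IdentificationRecord("p1", "A", 2, 4),
            IdentificationRecord("p2", "B", 1, 5),
        ]
        m = build_matrix(recs)
        assert m.stage == "raw"
        assert m.data.loc["p2", ("A", 1)] == 0
        assert m.data.loc["p1", ("A", 2)] == 4

    def test_duplicates_summed_with_warning(self):
        recs = [IdentificationRecord("p", "b", 1, 3), IdentificationRecord("p", "b", 1, 4)]
        with pytest.warns(UserWarning, match="duplicate"):
            m = build_matrix(recs)
        assert m.data.loc["p", ("b", 1)] == 7

    def test_decoys_rejected(self):
        with pytest.raises(ValueError, match="decoy"):
            build_matrix([IdentificationRecord("REV_p", "b", 1, 3, decoy=True)])

    def test_empty_records_give_empty_matrix(self):
        m = build_matrix([])
        assert m.data.shape == (0, 0)


class TestNormalizationStages:
    def test_quantitative_values_scale_to_mean_total(self):
        cols = pd.MultiIndex.from_tuples([("A", 1), ("B", 1)], names=["bait", "replicate"])
        df = pd.DataFrame([[4.0, 12.0], [6.0, 18.0]], index=["p1", "p2"], columns=cols)
        qv = quantitative_values(CountMatrix(df, "raw"))
        # totals {10, 30}: mean 20 -> factors {2, 2/3}; all totals become 20
        assert np.allclose(qv.data.sum(axis=0), [20.0, 20.0])
        assert np.allclose(qv.data[("A", 1)], [8.0, 12.0])

    def test_equal_totals_leave_matrix_unchanged(self, small_raw_matrix):
        df = small_raw_matrix.data.copy()
        df[:] = 3.0
        qv = quantitative_values(CountMatrix(df, "raw"))
        assert np.allclose(qv.data, df)

    def test_single_column_unchanged(self):
        cols = pd.MultiIndex.from_tuples([("A", 1)], names=["bait", "replicate"])
        df = pd.DataFrame([[7.0]], index=["p"], columns=cols)
        assert np.allclose(quantitative_values(CountMatrix(df, "raw")).data, df)

    def test_percent_columns_sum_to_100(self, small_raw_matrix):
        pct = percent_of_total(small_raw_matrix)
        totals = pct.data.sum(axis=0)
        assert np.allclose(totals[totals > 0], 100.0, atol=1e-9)

    def test_zero_column_stays_zero(self):
        cols = pd.MultiIndex.from_tuples([("A", 1), ("A", 2)], names=["bait", "replicate"])
        df = pd.DataFrame([[3.0, 0.0]], index=["p"], columns=cols)
        pct = percent_of_total(CountMatrix(df, "raw"))
        assert pct.data[("A", 2)].iloc[0] == 0.0

    def test_replicate_mean(self, small_raw_matrix):
        mean = mean_across_replicates(percent_of_total(small_raw_matrix))
        assert mean.stage == "replicate_mean"
        assert list(mean.data.columns) == ["A", "B"]
        pct = percent_of_total(small_raw_matrix)
        expect = (pct.data[("A", 1)] + pct.data[("A", 2)]) / 2
        assert np.allclose(mean.data["A"], expect)

    def test_unequal_replicate_counts_each_averaged_over_own(self):
        cols = pd.MultiIndex.from_tuples(
            [("A", 1), ("A", 2), ("A", 3), ("B", 1)], names=["bait", "replicate"]
        )
        df = pd.DataFrame([[30.0, 60.0, 90.0, 10.0]], index=["p"], columns=cols)
        mean = mean_across_replicates(CountMatrix(
            100.0 * df / df.sum(axis=0), "percent_of_total"))
        assert np.allclose(mean.data.loc["p"], [100.0, 100.0])

    def test_replicate_mean_is_permutation_invariant(self):
        rng = np.random.default_rng(3)
        m = random_count_matrix(rng, n_proteins=5, n_baits=3)
        pct = percent_of_total(m)
        shuffled = CountMatrix(pct.data[pct.data.columns[::-1]], "percent_of_total")
        a = mean_across_replicates(pct).data
        b = mean_across_replicates(shuffled).data[a.columns]
        assert np.allclose(a, b)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_normalization_collapse(self, seed):
        """percent_of_total(quantitative_values(M)) == percent_of_total(M)."""
        m = random_count_matrix(np.random.default_rng(seed))
        direct = percent_of_total(m).data.to_numpy()
        via_qv = percent_of_total(quantitative_values(m)).data.to_numpy()
        assert np.allclose(direct, via_qv, atol=1e-9)

    def test_stage_preconditions(self, small_raw_matrix):
        pct = percent_of_total(small_raw_matrix)
        with pytest.raises(ValueError, match="raw"):
            quantitative_values(pct)
        with pytest.raises(ValueError, match="percent_of_total"):
            mean_across_replicates(small_raw_matrix)

    def test_matrix_tsv_round_trip(self, small_raw_matrix, tmp_path):
        mean = mean_across_replicates(percent_of_total(small_raw_matrix))
        mean.to_tsv(tmp_path / "m.tsv")
        back = CountMatrix.from_tsv(tmp_path / "m.tsv", "replicate_mean")
        assert np.allclose(back.data, mean.data)
        assert list(back.data.columns) == list(mean.data.columns)


class TestFdr:
    def test_d_over_t(self):
        assert compute_fdr(1000, 10, "d_over_t") == pytest.approx(0.01)

    def test_zero_decoys_give_zero(self):
        assert compute_fdr(500, 0, "d_over_t") == 0.0
        assert compute_fdr(500, 0, "2d_over_td") == 0.0

    def test_concatenated_convention(self):
        assert compute_fdr(990, 10, "2d_over_td") == pytest.approx(0.02)

    def test_undefined_cases(self):
        with pytest.raises(ValueError):
            compute_fdr(0, 5, "d_over_t")
        with pytest.raises(ValueError):
            compute_fdr(0, 0, "2d_over_td")


class TestHi3:
    def test_mean_of_top_three(self):
        assert hi3_quantify([10, 8, 6, 1]) == pytest.approx(8.0)

    def test_two_peptides_use_both(self):
        assert hi3_quantify([10, 8]) == pytest.approx(9.0)

    def test_single_peptide_flagged_low_evidence(self):
        with pytest.warns(UserWarning, match="low-evidence"):
            assert hi3_quantify([5.0]) == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hi3_quantify([])

    @given(st.lists(st.floats(0.001, 1e6), min_size=2, max_size=10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_invariant_and_monotone(self, responses):
        base = hi3_quantify(responses)
        assert hi3_quantify(list(reversed(responses))) == pytest.approx(base)
        bumped = [responses[0] + 1.0] + responses[1:]
        assert hi3_quantify(bumped) >= base


class TestAbsoluteQuantity:
    def test_calibrant_level_recovered(self):
        assert absolute_quantity(4.2, 4.2) == pytest.approx(50.0)

    def test_linearity(self):
        assert absolute_quantity(8.4, 4.2) == pytest.approx(100.0)
        assert absolute_quantity(0.0, 4.2) == 0.0

    def test_nonpositive_calibrant_rejected(self):
        with pytest.raises(ValueError):
            absolute_quantity(1.0, 0.0)


class TestRanking:
    def test_descending_ranks(self):
        est = [AbundanceEstimate(p, q, q) for p, q in [("a", 3.0), ("b", 1.0), ("c", 2.0)]]
        ranked = {e.protein: e.rank for e in abundance_rank(est)}
        assert ranked == {"a": 1, "c": 2, "b": 3}

    def test_tie_broken_by_accession(self):
        est = [AbundanceEstimate(p, 2.0, 2.0) for p in ("zzz", "aaa")]
        ranked = abundance_rank(est)
        assert [e.protein for e in ranked] == ["aaa", "zzz"]

    def test_top_n_membership(self):
        est = [AbundanceEstimate(p, q, q) for p, q in [("a", 3.0), ("b", 1.0), ("c", 2.0)]]
        assert top_n_membership(est, ["a", "b"], 2) == ["a"]
        assert top_n_membership(est, ["a", "b", "c"], 10) == ["a", "b", "c"]
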
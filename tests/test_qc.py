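"""Count validation, run-summary arithmetic, activity calls, quantile
normalization and depth binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from droughtseq.errors import ConfigError, DesignError, FormatError
from droughtseq.qc import (
    CountMatrix,
    call_expressed,
    compute_depth,
    depth_bins,
    qc_summary,
    quantile_normalize,
    quantile_normalize_array,
    read_counts,
)
from droughtseq.reference_data import (
    STUDY_GENE_TALLIES,
    STUDY_LANE_SUMMARY,
    expressed_percentages,
)


class TestReadCounts:
    def test_well_formed_round_trip(self, toy_matrix, tmp_path):
        toy_matrix.counts.to_csv(tmp_path / "c.tsv", sep="\t")
        toy_matrix.samples.to_csv(tmp_path / "s.tsv", sep="\t", index=False)
        loaded = read_counts(tmp_path / "c.tsv", tmp_path / "s.tsv")
        assert loaded.counts.shape == (3, 4)
        pd.testing.assert_frame_equal(loaded.counts, toy_matrix.counts)

    def test_negative_count_rejected(self, toy_matrix):
        bad = toy_matrix.counts.copy()
        bad.iloc[0, 0] = -1
        with pytest.raises(FormatError, match="negative"):
            CountMatrix(counts=bad, samples=toy_matrix.samples)

    def test_non_integer_count_rejected(self, toy_matrix):
        bad = toy_matrix.counts.astype(float)
        bad.iloc[0, 0] = 1.5
        with pytest.raises(FormatError, match="integral"):
            CountMatrix(counts=bad, samples=toy_matrix.samples)

    def test_lane_sheet_mismatch_rejected(self, toy_matrix):
        with pytest.raises(DesignError, match="mismatch"):
            CountMatrix(
                counts=toy_matrix.counts,
                samples=toy_matrix.samples.iloc[:3],
            )

    def test_duplicate_gene_ids_rejected(self, toy_matrix):
        dup = pd.concat([toy_matrix.counts, toy_matrix.counts.iloc[[0]]])
        with pytest.raises(FormatError, match="duplicate"):
            CountMatrix(counts=dup, samples=toy_matrix.samples)


class TestQcSummary:
    def test_study_grand_totals(self):
        """The published per-sample totals sum to the printed grand totals
        and mapping percentages."""
        out = qc_summary(STUDY_LANE_SUMMARY)
        total = out.loc["total"]
        assert total["total_reads"] == pytest.approx(689.5)
        assert total["purity_filtered"] == pytest.approx(535.9)
        assert total["uniquely_mapped"] == pytest.approx(462.9)
        assert total["pct_uniquely_mapped_of_total"] == 67.1
        # uniquely mapped / purity filtered is the printed "~86-87%"
        assert 86.0 <= total["pct_uniquely_mapped_of_pf"] <= 87.0

    def test_grand_total_is_sum_of_samples(self):
        out = qc_summary(STUDY_LANE_SUMMARY)
        for col in ("total_reads", "uniquely_mapped"):
            assert out.loc["total", col] == pytest.approx(
                out.drop(index="total")[col].sum()
            )

    def test_zero_totals_give_undefined_fractions(self):
        zeros = STUDY_LANE_SUMMARY.iloc[:2] * 0.0
        out = qc_summary(zeros)
        assert out["pct_uniquely_mapped_of_total"].isna().all()

    def test_missing_category_rejected(self):
        with pytest.raises(FormatError, match="missing"):
            qc_summary(STUDY_LANE_SUMMARY.drop(columns=["uniquely_mapped"]))


class TestCallExpressed:
    def test_single_low_count_not_expressed(self, toy_matrix):
        # gB is all-zero; gene with a single count of 1 stays silent too
        m = toy_matrix
        m.counts.loc["gB", "l1"] = 1
        expressed, _ = call_expressed(m, min_raw=2)
        assert "gB" not in expressed
        assert {"gA", "gC"} <= expressed

    def test_zero_threshold_is_vacuous(self, toy_matrix):
        expressed, _ = call_expressed(toy_matrix, min_raw=0)
        assert expressed == set(toy_matrix.genes)

    def test_monotone_in_threshold(self, small_experiment):
        matrix, _, _ = small_experiment
        previous = None
        for min_raw in (0, 2, 10, 100):
            expressed, _ = call_expressed(matrix, min_raw=min_raw)
            if previous is not None:
                assert expressed <= previous
            previous = expressed

    def test_breakdown_percentages(self, small_experiment):
        matrix, _, annotations = small_experiment
        expressed, breakdown = call_expressed(matrix, annotations.annotation)
        row = breakdown.loc["high"]
        assert row["pct_of_annotated"] == pytest.approx(
            100.0 * row["expressed"] / row["annotated"], abs=0.05
        )

    def test_study_percentage_arithmetic(self):
        """25,568/27,640 high-confidence expressed genes is the printed
        92.5%; the silent and low-depth tallies match their percentages."""
        pct = expressed_percentages()
        assert pct["pct_high_confidence_expressed"] == 92.5
        assert pct["pct_models_silent"] == 17.0
        assert pct["pct_silent_low_confidence"] == 67.4
        assert pct["pct_low_depth_of_detected"] == 11.2
        t = STUDY_GENE_TALLIES
        assert t["expressed_high_confidence"] / t["high_confidence_models"] \
            == pytest.approx(0.925, abs=5e-4)


class TestQuantileNormalize:
    def test_two_lane_mean_of_order_statistics(self):
        out = quantile_normalize_array(
            np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        )
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_lanes_unchanged(self):
        col = np.array([3.0, 1.0, 7.0, 2.0])
        out = quantile_normalize_array(np.column_stack([col, col, col]))
        np.testing.assert_allclose(out, np.column_stack([col, col, col]))

    def test_ties_match_reference_implementation(self):
        """Frozen output of limma::normalizeQuantiles(ties=TRUE) on two
        tie-bearing matrices (limma 3.58.1)."""
        out = quantile_normalize_array(
            np.array([[5.0, 2.0], [1.0, 8.0], [3.0, 4.0], [3.0, 6.0]])
        )
        np.testing.assert_allclose(
            out, np.array([[6.5, 1.5], [1.5, 6.5], [4.0, 3.5], [4.0, 4.5]])
        )
        out3 = quantile_normalize_array(np.array(
            [[0, 10, 1], [0, 2, 1], [7, 2, 1], [3, 5, 1], [3, 9, 1],
             [3, 0, 8]], dtype=float,
        ))
        expected3 = np.array(
            [
                [2 / 3, 25 / 3, 2.0],
                [2 / 3, 1.5, 2.0],
                [25 / 3, 1.5, 2.0],
                [3.0, 3.0, 2.0],
                [3.0, 13 / 3, 2.0],
                [3.0, 1 / 3, 25 / 3],
            ]
        )
        np.testing.assert_allclose(out3, expected3)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.permutations(list(range(12))), st.permutations(list(range(12))),
           st.permutations(list(range(12))))
    def test_rank_order_and_distribution_invariants(self, c0, c1, c2):
        """On tie-free lanes, normalization preserves within-lane rank
        order and makes every lane's sorted vector identical (ties relax
        the sorted-vector identity to an interpolated approximation)."""
        values = np.column_stack([c0, c1, c2]).astype(float) ** 1.5
        out = quantile_normalize_array(values)
        sorted_cols = np.sort(out, axis=0)
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0],
                                       atol=1e-9)
        for j in range(out.shape[1]):
            order = np.argsort(values[:, j], kind="stable")
            assert np.all(np.diff(out[order, j]) >= -1e-12)

    def test_equalizes_scaled_lane_medians(self, small_experiment):
        """The planted library-size imbalance (one run scaled x1.3) leaves
        >20% median spread before normalization and <2% after (residual
        spread comes from tie interpolation on integer counts)."""
        matrix, _, _ = small_experiment
        raw_medians = matrix.counts.median(axis=0)
        assert raw_medians.max() / raw_medians.min() > 1.2
        quantile_normalize(matrix)
        medians = matrix.normalized.median(axis=0)
        assert (medians.max() - medians.min()) / medians.median() < 0.02

    def test_single_lane_warns(self, toy_matrix):
        single = CountMatrix(
            counts=toy_matrix.counts[["l1"]],
            samples=toy_matrix.samples.iloc[[0]],
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            quantile_normalize(single)
        pd.testing.assert_frame_equal(
            single.normalized, single.counts.astype(float)
        )


class TestDepth:
    def test_depth_definition(self, toy_matrix):
        # 100 reads of 50 bp on a 1000-bp gene = 5X
        lengths = pd.Series([1000, 1000, 1000],
                            index=["gA", "gB", "gC"])
        toy_matrix.counts.loc["gA"] = [100, 100, 100, 100]
        depth = compute_depth(toy_matrix, lengths, read_length=50,
                              use_normalized=False)
        assert depth.loc["gA", "shoot:ABA"] == pytest.approx(5.0)
        assert depth.loc["gB", "shoot:ABA"] == 0.0

    def test_bins_partition_genes(self, small_experiment):
        matrix, truth, _ = small_experiment
        depth = compute_depth(matrix, truth.gene_lengths,
                              use_normalized=False)
        bins = depth_bins(depth)
        assert (bins.sum(axis=0) == len(matrix.genes)).all()

    def test_bin_assignment_edges(self):
        depth = pd.DataFrame({"s": [0.0, 0.5, 2.0, 5.0, 60.0]})
        bins = depth_bins(depth)["s"]
        assert bins["0x"] == 1
        assert bins["<=1x"] == 1
        assert bins["1-2x"] == 1      # 2.0 falls in (1, 2]
        assert bins["2-5x"] == 1
        assert bins[">50x"] == 1

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ConfigError, match="increasing"):
            depth_bins(pd.DataFrame({"s": [1.0]}), edges=(0.0, 2.0, 1.0))
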
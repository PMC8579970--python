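"""Indicator inference: abundance transforms, anomalies, critical time
points, SSP ranking, absolute abundance, Tukey outliers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import soursentinel as ss
from soursentinel.io_model import CountTable


def _table(values, taxa, corrected=False):
    data = pd.DataFrame(
        np.atleast_2d(np.asarray(values, float)),
        index=[f"s{i}" for i in range(np.atleast_2d(values).shape[0])],
        columns=taxa,
    )
    return CountTable(data, corrected=corrected)


def _ann(rows):
    return pd.DataFrame(
        rows, columns=["taxon_id", "genome_label", "is_srb", "copy_number", "has_dsr"]
    ).set_index("taxon_id")


class TestCopyNumberCorrection:
    def test_direct_division(self):
        ann = _ann([("a", "A", True, 2, True), ("b", "B", False, 3, False)])
        out = ss.correct_copy_number(_table([[10, 9]], ["a", "b"]), ann)
        assert out.data.iloc[0].tolist() == [5.0, 3.0]
        assert out.corrected

    def test_unit_copies_identity(self):
        ann = _ann([("a", "A", True, 1, True), ("b", "B", False, 1, False)])
        out = ss.correct_copy_number(_table([[4, 7]], ["a", "b"]), ann)
        assert out.data.iloc[0].tolist() == [4.0, 7.0]

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(8)]
        copies = rng.integers(1, 9, 8)
        ann = _ann([(t, t.upper(), False, c, False) for t, c in zip(taxa, copies)])
        raw = rng.integers(0, 100, (5, 8)).astype(float)
        out = ss.correct_copy_number(_table(raw, taxa), ann)
        np.testing.assert_allclose(out.data.to_numpy() * copies, raw, atol=1e-12)

    def test_double_correction_refused(self):
        ann = _ann([("a", "A", True, 2, True)])
        with pytest.raises(ss.ValidationError, match="already"):
            ss.correct_copy_number(_table([[1]], ["a"], corrected=True), ann)

    def test_missing_annotation_rejected(self):
        ann = _ann([("a", "A", True, 2, True)])
        with pytest.raises(ss.ValidationError):
            ss.correct_copy_number(_table([[1, 2]], ["a", "zz"]), ann)


class TestGenomeAggregation:
    def test_variants_sum(self):
        ann = _ann([("a", "G", True, 1, True), ("b", "G", True, 1, True)])
        out = ss.aggregate_to_genomes(_table([[3, 4]], ["a", "b"], corrected=True), ann)
        assert out.data["G"].iloc[0] == 7.0

    def test_one_variant_per_genome_relabels(self):
        ann = _ann([("a", "A", True, 1, True), ("b", "B", False, 1, False)])
        out = ss.aggregate_to_genomes(_table([[3, 4]], ["a", "b"], corrected=True), ann)
        assert sorted(out.data.columns) == ["A", "B"]
        assert out.data.iloc[0].sum() == 7.0

    def test_row_totals_conserved(self):
        rng = np.random.default_rng(1)
        taxa = [f"t{i}" for i in range(10)]
        ann = _ann([(t, f"G{i % 3}", False, 1, False) for i, t in enumerate(taxa)])
        raw = rng.random((4, 10))
        out = ss.aggregate_to_genomes(_table(raw, taxa, corrected=True), ann)
        np.testing.assert_allclose(out.data.sum(axis=1), raw.sum(axis=1), atol=1e-12)

    def test_uncorrected_input_refused(self):
        ann = _ann([("a", "A", True, 1, True)])
        with pytest.raises(ss.ValidationError, match="corrected"):
            ss.aggregate_to_genomes(_table([[1]], ["a"]), ann)


class TestRelativeAbundance:
    def test_percent_values(self):
        out = ss.relative_abundance(_table([[1, 3]], ["a", "b"]))
        assert out.data.iloc[0].tolist() == [25.0, 75.0]
        assert out.percent

    def test_single_taxon_is_100(self):
        assert ss.relative_abundance(_table([[9]], ["a"])).data.iloc[0, 0] == 100.0

    def test_scale_invariance(self):
        a = ss.relative_abundance(_table([[2, 3, 5]], ["a", "b", "c"]))
        b = ss.relative_abundance(_table([[20, 30, 50]], ["a", "b", "c"]))
        np.testing.assert_allclose(a.data, b.data)

    def test_zero_row_named_in_error(self):
        with pytest.raises(ss.DomainError, match="s1"):
            ss.relative_abundance(_table([[1, 2], [0, 0]], ["a", "b"]))


class TestAnomalySeries:
    def test_hand_example(self):
        out = ss.anomaly_series(pd.Series([2.0, 4.0, 6.0], index=[0, 1, 2]))
        np.testing.assert_allclose(out["anomaly"], [-0.5, 0.0, 0.5])
        assert (out["window_mean"] == 4.0).all()

    def test_constant_series_zero(self):
        out = ss.anomaly_series(pd.Series([3.0, 3.0, 3.0], index=[0, 1, 2]))
        np.testing.assert_allclose(out["anomaly"], 0.0)

    def test_restricted_window(self):
        out = ss.anomaly_series(pd.Series([2.0, 4.0, 60.0], index=[0, 1, 2]), window=[0, 1])
        assert (out["window_mean"] == 3.0).all()
        np.testing.assert_allclose(out["anomaly"], [-1 / 3, 1 / 3, 19.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ss.DomainError):
            ss.anomaly_series(pd.Series([0.0, 0.0], index=[0, 1]))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 1000, allow_nan=False), min_size=2, max_size=40)
    )
    def test_zero_sum_identity(self, values):
        """Anomalies over the averaging window always sum to zero."""
        out = ss.anomaly_series(pd.Series(values, index=range(len(values))))
        assert abs(out["anomaly"].sum()) <= 1e-9 * len(values)


class TestCriticalTimePoints:
    def test_strictly_above_mean(self):
        """TM values (1, 5, 3) have mean 3; only the 5 is critical
        (equality with the mean does not qualify)."""
        x = pd.Series([1.0, 5.0, 3.0], index=[10, 12, 14])
        phases = pd.Series(["TM", "TM", "TM"], index=[10, 12, 14])
        assert ss.detect_critical_time_points(x, phases) == [12]

    def test_constant_tm_none(self):
        x = pd.Series([2.0, 2.0], index=[0, 1])
        phases = pd.Series(["TM", "TM"], index=[0, 1])
        assert ss.detect_critical_time_points(x, phases) == []

    def test_non_tm_points_ignored(self):
        x = pd.Series([99.0, 1.0, 5.0], index=[0, 10, 12])
        phases = pd.Series(["S", "TM", "TM"], index=[0, 10, 12])
        assert ss.detect_critical_time_points(x, phases) == [12]

    def test_empty_tm_warns_and_returns_empty(self):
        x = pd.Series([1.0, 2.0], index=[0, 1])
        phases = pd.Series(["S", "S"], index=[0, 1])
        with pytest.warns(UserWarning, match="no TM phase"):
            assert ss.detect_critical_time_points(x, phases) == []


class TestSSPSelection:
    def _ann(self):
        return _ann(
            [
                ("a", "SRB-A", True, 1, True),
                ("b", "SRB-B", True, 1, True),
                ("c", "Other", False, 1, False),
            ]
        )

    def test_ranking_by_tm_mean(self):
        table = pd.DataFrame(
            {"SRB-A": [4.0, 4.0], "SRB-B": [2.0, 2.0], "Other": [94.0, 94.0]},
            index=[10, 12],
        )
        phases = pd.Series(["TM", "TM"], index=[10, 12])
        out = ss.select_ssp_candidates(table, self._ann(), phases)
        assert [g for g, _ in out] == ["SRB-A", "SRB-B"]
        assert out[0][1] == pytest.approx(4.0)

    def test_single_srb(self):
        table = pd.DataFrame({"SRB-A": [1.0], "Other": [99.0]}, index=[10])
        out = ss.select_ssp_candidates(
            table, _ann([("a", "SRB-A", True, 1, True), ("c", "Other", False, 1, False)]),
            pd.Series(["TM"], index=[10]),
        )
        assert out == [("SRB-A", 1.0)]

    def test_tie_broken_lexicographically(self):
        table = pd.DataFrame({"SRB-B": [2.0], "SRB-A": [2.0], "Other": [96.0]}, index=[10])
        out = ss.select_ssp_candidates(table, self._ann(), pd.Series(["TM"], index=[10]))
        assert [g for g, _ in out] == ["SRB-A", "SRB-B"]

    def test_floor_filters(self):
        table = pd.DataFrame({"SRB-A": [4.0], "SRB-B": [0.5], "Other": [95.5]}, index=[10])
        out = ss.select_ssp_candidates(
            table, self._ann(), pd.Series(["TM"], index=[10]), floor=1.0
        )
        assert [g for g, _ in out] == ["SRB-A"]

    def test_no_srb_rejected(self):
        table = pd.DataFrame({"Other": [100.0]}, index=[10])
        with pytest.raises(ss.ValidationError, match="SRB"):
            ss.select_ssp_candidates(
                table,
                _ann([("c", "Other", False, 1, False)]),
                pd.Series(["TM"], index=[10]),
            )


class TestCellAbundance:
    def test_direct_product(self):
        assert ss.ssp_cell_abundance(2.0, 1e6) == pytest.approx(2e4)

    def test_extremes(self):
        assert ss.ssp_cell_abundance(0.0, 5e6) == 0.0
        assert ss.ssp_cell_abundance(100.0, 5e6) == pytest.approx(5e6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ss.DomainError):
            ss.ssp_cell_abundance(120.0, 1e6)


def _tukey_oracle(values):
    """Independently coded quartile oracle: manual linear interpolation
    between order statistics at positions 1 + (n-1)q."""
    xs = sorted(values)
    n = len(xs)

    def quartile(q):
        pos = (n - 1) * q
        lo = int(np.floor(pos))
        hi = int(np.ceil(pos))
        return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])

    q1, q3 = quartile(0.25), quartile(0.75)
    iqr = q3 - q1
    return [v < q1 - 1.5 * iqr or v > q3 + 1.5 * iqr for v in values]


class TestTukeyOutliers:
    def test_hand_example(self):
        """(1,2,3,4,100): Q1=2, Q3=4, fences [-1, 7] -> only 100 flagged."""
        flags = ss.flag_tukey_outliers([1, 2, 3, 4, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_vector_none_flagged(self):
        assert not ss.flag_tukey_outliers([5.0] * 6).any()

    def test_short_vector_warns_all_pass(self):
        with pytest.warns(UserWarning):
            assert not ss.flag_tukey_outliers([1.0, 100.0]).any()

    def test_empty_rejected(self):
        with pytest.raises(ss.DomainError):
            ss.flag_tukey_outliers([])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        values = np.round(rng.normal(0, 10, n), 2)
        assert ss.flag_tukey_outliers(values).tolist() == _tukey_oracle(values)


class TestReportAssembly:
    def test_report_on_small_synthetic(self, small_experiment):
        bundle, truth = small_experiment
        eff = bundle.samples[bundle.samples["sample_type"] == "effluent"]
        phases = ss.assign_phases(
            bundle.sulfide, bundle.schedule, times=eff[["column_id", "time_point"]]
        )
        report = ss.build_indicator_report(bundle, phases)
        assert sorted(report.columns) == bundle.treated_columns()
        for cid, col in report.columns.items():
            assert col.ssp_rank, cid
            assert set(col.critical_time_points) <= set(
                phases.loc[
                    (phases["column_id"] == cid) & (phases["phase"] == "TM"),
                    "time_point",
                ]
            )
        # anomaly zero-sum identity holds for every emitted series
        for (cid, sig), grp in report.anomalies.groupby(["column_id", "signal"]):
            assert abs(grp["anomaly"].sum()) <= 1e-9 * len(grp)

    def test_pipeline_conservation(self, small_experiment):
        """Aggregation conserves per-sample totals and relative
        abundances sum to 100 at the end of the transform chain."""
        bundle, _ = small_experiment
        corrected = ss.correct_copy_number(bundle.counts, bundle.annotations)
        agg = ss.aggregate_to_genomes(corrected, bundle.annotations)
        np.testing.assert_allclose(
            agg.data.sum(axis=1), corrected.data.sum(axis=1), rtol=1e-12
        )
        pct = ss.relative_abundance(agg)
        np.testing.assert_allclose(pct.data.sum(axis=1), 100.0, atol=1e-9)
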
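"""DSR pathway abundance, average anomalies, and trend smoothing."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import soursentinel as ss
from soursentinel.indicators import genome_percent_table
from soursentinel.pathways import average_anomaly, dsr_anomalies, smooth_trend

from conftest import small_config


def _ann(rows):
    return pd.DataFrame(
        rows, columns=["taxon_id", "genome_label", "is_srb", "copy_number", "has_dsr"]
    ).set_index("taxon_id")


class TestDSRRelativeAbundance:
    def test_single_contributor(self):
        table = pd.DataFrame({"A": [30.0], "B": [70.0]}, index=["s"])
        ann = _ann([("a", "A", True, 1, True), ("b", "B", False, 1, False)])
        assert ss.dsr_relative_abundance(table, ann).iloc[0] == pytest.approx(30.0)

    def test_no_dsr_genomes_zero(self):
        table = pd.DataFrame({"B": [100.0]}, index=["s"])
        ann = _ann([("b", "B", False, 1, False)])
        assert ss.dsr_relative_abundance(table, ann).iloc[0] == 0.0

    def test_additivity(self):
        table = pd.DataFrame({"A": [10.0], "B": [15.0], "C": [75.0]}, index=["s"])
        ann = _ann(
            [
                ("a", "A", True, 1, True),
                ("b", "B", True, 1, True),
                ("c", "C", False, 1, False),
            ]
        )
        assert ss.dsr_relative_abundance(table, ann).iloc[0] == pytest.approx(25.0)

    def test_bounded_by_100(self, small_experiment):
        bundle, _ = small_experiment
        pct = genome_percent_table(bundle)
        dsr = ss.dsr_relative_abundance(pct.data, bundle.annotations)
        assert ((dsr >= 0) & (dsr <= 100 + 1e-9)).all()

    def test_inconsistent_annotation_rejected(self):
        table = pd.DataFrame({"A": [100.0]}, index=["s"])
        ann = _ann([("a1", "A", True, 1, True), ("a2", "A", True, 1, False)])
        with pytest.raises(ss.ValidationError, match="inconsistent"):
            ss.dsr_relative_abundance(table, ann)


class TestAverageAnomaly:
    def _frame(self, entries):
        return pd.DataFrame(
            [
                {"column_id": c, "signal": "DSR", "time_point": t, "anomaly": a, "window_mean": 1.0}
                for c, t, a in entries
            ]
        )

    def test_two_point_mean_and_sd(self):
        out = ss.average_anomaly(self._frame([("c1", 0, 0.5), ("c2", 0, -0.5)]))
        assert out["mean"].iloc[0] == pytest.approx(0.0)
        assert out["sd"].iloc[0] == pytest.approx(np.sqrt(0.5), abs=1e-6)
        assert out["n"].iloc[0] == 2

    def test_single_column_sd_zero(self):
        out = ss.average_anomaly(self._frame([("c1", 0, 0.8)]))
        assert out["mean"].iloc[0] == pytest.approx(0.8)
        assert out["sd"].iloc[0] == 0.0

    def test_column_order_invariance(self):
        a = ss.average_anomaly(self._frame([("c1", 0, 0.1), ("c2", 0, 0.4), ("c1", 2, 0.2)]))
        b = ss.average_anomaly(self._frame([("c2", 0, 0.4), ("c1", 2, 0.2), ("c1", 0, 0.1)]))
        pd.testing.assert_frame_equal(a, b)

    def test_missing_column_omitted_from_time_point(self):
        out = ss.average_anomaly(self._frame([("c1", 0, 0.1), ("c2", 0, 0.3), ("c1", 2, 0.6)]))
        assert out.set_index("time_point").loc[2, "n"] == 1

    def test_unobserved_time_point_warns(self):
        with pytest.warns(UserWarning, match="no column"):
            out = ss.average_anomaly(self._frame([("c1", 0, 0.1)]), times=[0, 5])
        assert out["time_point"].tolist() == [0]


class TestSmoothTrend:
    def test_linear_data_reproduced(self):
        t = np.linspace(0, 10, 50)
        y = 2.0 * t + 1.0
        fit = smooth_trend(t, y)
        np.testing.assert_allclose(fit.fit, y, atol=1e-6)

    def test_constant_data(self):
        t = np.linspace(0, 10, 30)
        fit = smooth_trend(t, np.full(30, 3.0))
        np.testing.assert_allclose(fit.fit, 3.0, atol=1e-6)
        assert (fit.lower <= fit.fit).all() and (fit.fit <= fit.upper).all()

    def test_noise_reduction_on_sine(self):
        rng = np.random.default_rng(4)
        t = np.linspace(0, 10, 100)
        truth = np.sin(t)
        y = truth + rng.normal(0, 0.1, 100)
        fit = smooth_trend(t, y)
        rmse_fit = np.sqrt(np.mean((fit.fit - truth) ** 2))
        rmse_raw = np.sqrt(np.mean((y - truth) ** 2))
        assert rmse_fit < rmse_raw

    def test_band_contains_fit(self):
        rng = np.random.default_rng(5)
        t = np.arange(30.0)
        fit = smooth_trend(t, rng.normal(size=30))
        assert (fit.lower <= fit.fit).all() and (fit.fit <= fit.upper).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ss.ValidationError):
            smooth_trend([0, 1, 2, 3], [1, 2, 3, 4])

    def test_comparable_to_statsmodels_gam(self):
        """On noisy data the fit tracks a statsmodels penalized-spline
        GAM fit of the same basis dimension."""
        from statsmodels.gam.api import BSplines, GLMGam

        rng = np.random.default_rng(6)
        t = np.linspace(0, 10, 80)
        y = np.sin(t) + rng.normal(0, 0.15, 80)
        mine = smooth_trend(t, y, df=10)
        bs = BSplines(t[:, None], df=[10], degree=[3])
        gam = GLMGam(y, exog=np.ones((80, 1)), smoother=bs, alpha=[1.0])
        gam.scale = gam.fit().scale
        alpha = gam.select_penweight()[0]
        res = GLMGam(y, exog=np.ones((80, 1)), smoother=bs, alpha=alpha).fit()
        theirs = np.column_stack([np.ones(80), bs.basis]) @ res.params
        assert np.sqrt(np.mean((mine.fit - theirs) ** 2)) < 0.1


class TestAnomalyPeakRecovery:
    def test_treated_average_peaks_on_dispersal_day(self):
        """The post-treatment maximum of the cross-column average DSR
        anomaly lands on an injected dispersal day."""
        cfg = small_config(seed=21)
        bundle, truth = ss.generate_experiment(cfg)
        pct = genome_percent_table(bundle)
        frame = dsr_anomalies(bundle, pct.data, columns=bundle.treated_columns())
        avg = average_anomaly(frame)
        post = avg[avg["time_point"] >= cfg.nitrate_start_day]
        tmax = int(post.loc[post["mean"].idxmax(), "time_point"])
        injected = {d for days in truth.dispersal_days.values() for d in days}
        assert tmax in injected

    def test_nontreated_peak_time_uniform_over_grid(self):
        """Across seeds, the time of the nontreated post-amendment peak
        is consistent with a uniform distribution over the grid
        (chi-square goodness of fit, alpha = 0.01, 50 seeds)."""
        n_bins, per_bin = 5, 5
        counts = np.zeros(n_bins)
        for seed in range(50):
            cfg = small_config(
                seed=1000 + seed,
                n_columns=4,
                n_treated=0,
                n_background_taxa=10,
                n_srb_taxa=3,
                harvest_days=(80, 80, 80, 80),
            )
            bundle, _ = ss.generate_experiment(cfg)
            pct = genome_percent_table(bundle)
            frame = dsr_anomalies(bundle, pct.data)
            avg = average_anomaly(frame)
            post = avg[avg["time_point"] >= cfg.nitrate_start_day].reset_index(drop=True)
            window = post.iloc[: n_bins * per_bin]
            counts[int(window["mean"].idxmax()) // per_bin] += 1
        assert counts.sum() == 50
        _, p = scipy.stats.chisquare(counts)
        assert p > 0.01
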
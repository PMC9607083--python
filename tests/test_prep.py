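import numpy as np
import pandas as pd
import pytest

from naive_reference import naive_rmse

from lagtox import prep
from lagtox.panel import SeriesId, SeriesPanel, WeeklySeries, weekly_index
from lagtox.prep import (IMPUTER_REGISTRY, PrepConfig, SchemaError,
                         coverage_filter, impute, make_missing_copies,
                         prepare_panel, read_records, remove_outliers,
                         resample_weekly, rmse, tune_imputer)
from lagtox.synth import SynthConfig, simulate_all


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

class TestReadRecords:
    def test_missing_column_names_the_column(self, tmp_path):
        f = tmp_path / "bad.csv"
        f.write_text("Date,Production Area,DSP Toxins\n")
        with pytest.raises(SchemaError, match="Species"):
            read_records(f, "toxins")

    def test_extra_column_ignored_with_warning(self, tmp_path, caplog):
        f = tmp_path / "t.csv"
        f.write_text("Date,Production Area,Species,DSP Toxins,Technician\n"
                     "2015-01-05,A,mussel,12.5,bob\n")
        with caplog.at_level("WARNING"):
            table = read_records(f, "toxins")
        assert "Technician" not in table.columns
        assert any("Technician" in r.message for r in caplog.records)

    def test_empty_file_with_header_is_empty_table(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("Date,Production Area,Species,DSP Toxins\n")
        assert len(read_records(f, "toxins")) == 0

    def test_non_numeric_measurement_becomes_missing(self, tmp_path):
        f = tmp_path / "t.csv"
        f.write_text("Date,Production Area,Species,DSP Toxins\n"
                     "2015-01-05,A,mussel,<LOQ\n")
        table = read_records(f, "toxins")
        assert np.isnan(table["DSP Toxins"].iloc[0])


# ---------------------------------------------------------------------------
# Weekly resampling
# ---------------------------------------------------------------------------

class TestResample:
    SID = SeriesId("A", "toxicity", "mussel")

    def _records(self, rows):
        return pd.DataFrame(rows, columns=["Date", "value"]).assign(
            Date=lambda d: pd.to_datetime(d["Date"]))

    def test_two_observations_in_one_week_averaged(self):
        rec = self._records([("2015-01-06", 10.0), ("2015-01-08", 20.0)])
        s = resample_weekly(rec, self.SID, "2015-01-05", "2015-01-18")
        np.testing.assert_array_equal(s.values, [15.0, np.nan])

    def test_empty_week_is_missing(self):
        rec = self._records([("2015-01-05", 1.0), ("2015-01-19", 3.0)])
        s = resample_weekly(rec, self.SID, "2015-01-05", "2015-01-25")
        assert np.isnan(s.values[1])

    def test_daily_constant_gives_constant_weekly(self):
        days = pd.date_range("2015-01-05", "2015-02-01", freq="D")
        rec = pd.DataFrame({"Date": days, "value": 5.0})
        s = resample_weekly(rec, self.SID, "2015-01-05", "2015-02-01")
        np.testing.assert_array_equal(s.values, np.full(4, 5.0))

    def test_out_of_span_observations_dropped(self):
        rec = self._records([("2014-12-01", 99.0), ("2015-01-05", 1.0)])
        s = resample_weekly(rec, self.SID, "2015-01-05", "2015-01-11")
        np.testing.assert_array_equal(s.values, [1.0])


# ---------------------------------------------------------------------------
# Outliers & coverage
# ---------------------------------------------------------------------------

class TestOutliers:
    def test_rule_none_is_identity(self, make_series):
        s = make_series([1.0, 2.0, 1e6])
        assert remove_outliers(s, "none") is s

    def test_constant_series_untouched_by_mad(self, make_series):
        s = make_series(np.full(20, 7.0))
        out = remove_outliers(s, ("mad", 5.0))
        np.testing.assert_array_equal(out.values, s.values)

    def test_single_extreme_among_identical_values_masked(self, make_series):
        vals = np.full(312, 10.0)
        vals[100] = 10_000.0
        out = remove_outliers(make_series(vals), ("mad", 5.0))
        assert np.isnan(out.values[100])
        assert np.isnan(out.values).sum() == 1

    def test_invalid_k_rejected(self, make_series):
        with pytest.raises(ValueError):
            remove_outliers(make_series([1.0, 2.0]), ("mad", 0.0))


class TestCoverage:
    def _panel_with_counts(self, idx312, counts):
        panel = SeriesPanel(idx312)
        for i, n_obs in enumerate(counts):
            vals = np.full(312, 1.0)
            vals[n_obs:] = np.nan
            panel.add(WeeklySeries(SeriesId(f"A{i}", "v"), idx312, vals))
        return panel

    def test_inclusive_threshold(self, idx312):
        panel = self._panel_with_counts(idx312, [240, 239, 312])
        kept = coverage_filter(panel, min_weeks=240)
        assert {sid.area for sid in kept.ids()} == {"A0", "A2"}

    def test_fully_observed_panel_unchanged(self, idx312):
        panel = self._panel_with_counts(idx312, [312, 312])
        assert len(coverage_filter(panel, 240)) == 2


# ---------------------------------------------------------------------------
# RMSE and masked copies
# ---------------------------------------------------------------------------

class TestRmse:
    def test_identical_vectors_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_computed_value(self):
        assert rmse([1, 2, 3], [1, 2, 5]) == pytest.approx(np.sqrt(4 / 3), abs=1e-12)

    def test_single_element(self):
        assert rmse([5.0], [3.0]) == 2.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    def test_matches_naive_loop_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(1, 50)
            x, y = rng.normal(size=(2, n)) * 10
            assert rmse(x, y) == pytest.approx(naive_rmse(list(x), list(y)), abs=1e-12)


class TestMissingCopies:
    def _gappy(self, make_series):
        vals = np.arange(100.0)
        vals[[5, 17, 44]] = np.nan
        return make_series(vals)

    def test_masks_disjoint_and_within_observed(self, make_series):
        s = self._gappy(make_series)
        trials = make_missing_copies(s, n_copies=5, hide_frac=0.1, seed=3)
        assert len(trials) == 5
        union = np.zeros(100, dtype=bool)
        for t in trials:
            assert not (t.mask & union).any()  # disjoint
            union |= t.mask
        assert not (union & ~s.observed_mask).any()  # never hides original gaps

    def test_deterministic_from_seed(self, make_series):
        s = self._gappy(make_series)
        a = make_missing_copies(s, seed=7)
        b = make_missing_copies(s, seed=7)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.mask, tb.mask)

    def test_refuses_sparse_series(self, make_series):
        vals = np.full(50, np.nan)
        vals[:5] = 1.0
        with pytest.raises(ValueError, match="observed"):
            make_missing_copies(make_series(vals))


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

class TestImpute:
    @pytest.mark.parametrize("method", sorted(IMPUTER_REGISTRY))
    def test_complete_series_identity(self, make_series, method):
        s = make_series(np.arange(60.0))
        out = impute(s, method)
        np.testing.assert_array_equal(out.values, s.values)

    def test_linear_midpoint(self, make_series):
        vals = np.array([1.0, 4.0, np.nan, 8.0, 2.0])
        out = impute(make_series(vals), "linear_interp")
        assert out.values[2] == 6.0

    @pytest.mark.parametrize("method", sorted(IMPUTER_REGISTRY))
    def test_no_missing_remain_and_observed_preserved(self, make_series, method):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=120)
        vals[rng.random(120) < 0.3] = np.nan
        vals[0] = np.nan  # leading gap exercises the edge fallback
        s = make_series(vals)
        out = impute(s, method, {"window": 5} if method == "moving_average" else None)
        assert not np.isnan(out.values).any()
        obs = s.observed_mask
        np.testing.assert_array_equal(out.values[obs], s.values[obs])

    def test_all_missing_rejected(self, make_series):
        with pytest.raises(ValueError, match="all-missing"):
            impute(make_series(np.full(20, np.nan)), "mean_fill")

    def test_unknown_method_rejected(self, make_series):
        with pytest.raises(ValueError, match="unknown"):
            impute(make_series([1.0, np.nan, 2.0]), "magic_fill")


class TestTuneImputer:
    def _noisy_sine(self, make_series, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.sin(np.arange(200) * 2 * np.pi / 52) * 10
        vals[rng.random(200) < 0.15] = np.nan
        return make_series(vals)

    def test_selected_never_worse_than_mean_fill(self, make_series):
        s = self._noisy_sine(make_series)
        rep = tune_imputer(s, strategy="grid", seed=1)
        mean_entry = next(c for c in rep.candidates if c["method"] == "mean_fill")
        assert rep.selected_rmse <= mean_entry["mean_rmse"]

    def test_selected_attains_minimum_evaluated_rmse(self, make_series):
        s = self._noisy_sine(make_series, seed=2)
        rep = tune_imputer(s, strategy="grid", seed=2)
        assert rep.selected_rmse == min(c["mean_rmse"] for c in rep.candidates)

    def test_matches_exhaustive_grid_oracle(self, make_series):
        # brute-force every (method, params) combination independently and
        # compare with the tuner's selection on a 2-candidate search
        s = self._noisy_sine(make_series, seed=3)
        candidates = ["linear_interp", "moving_average"]
        rep = tune_imputer(s, candidates=candidates, strategy="grid", seed=5)
        trials = make_missing_copies(s, n_copies=5, hide_frac=0.1, seed=5)
        best = None
        for method in candidates:
            _fn, grid = IMPUTER_REGISTRY[method]
            for params in prep._grid_points(grid):
                scores = []
                for t in trials:
                    hidden_vals = s.values.copy()
                    hidden_vals[t.mask] = np.nan
                    filled = impute(s.with_values(hidden_vals), method, params)
                    scores.append(rmse(s.values[t.mask], filled.values[t.mask]))
                score = float(np.mean(scores))
                if best is None or score < best[2]:
                    best = (method, params, score)
        assert rep.selected_method == best[0]
        assert rep.selected_params == best[1]
        assert rep.selected_rmse == pytest.approx(best[2], abs=1e-12)

    @pytest.mark.parametrize("strategy", ["grid", "random", "bayesian"])
    def test_deterministic_given_seed(self, make_series, strategy):
        s = self._noisy_sine(make_series, seed=4)
        a = tune_imputer(s, strategy=strategy, seed=9)
        b = tune_imputer(s, strategy=strategy, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_empty_candidates_rejected(self, make_series):
        with pytest.raises(ValueError, match="empty"):
            tune_imputer(self._noisy_sine(make_series), candidates=[])


# ---------------------------------------------------------------------------
# Whole chain
# ---------------------------------------------------------------------------

class TestPreparePanel:
    def test_no_missingness_means_no_reports(self, tmp_path):
        cfg = SynthConfig(seed=1, n_areas=2, missing_frac=0.0, block_gap_rate=0.0)
        sim = simulate_all(cfg, out_dir=tmp_path)
        pcfg = PrepConfig(start_date=cfg.start_date, end_date=cfg.end_date, strategy="grid")
        panel, reports = prepare_panel(sim["paths"], pcfg)
        assert reports == []
        for sid in panel.ids():
            if sid.variable == "toxicity":
                np.testing.assert_allclose(panel[sid].values, sim["toxicity"][sid].values)

    def test_planted_gaps_fully_imputed(self, tmp_path):
        cfg = SynthConfig(seed=2, n_areas=2)
        sim = simulate_all(cfg, out_dir=tmp_path)
        pcfg = PrepConfig(start_date=cfg.start_date, end_date=cfg.end_date, strategy="grid")
        panel, reports = prepare_panel(sim["paths"], pcfg)
        assert len(reports) > 0
        for s in panel:
            assert s.is_complete()

    def test_observed_values_preserved(self, tmp_path):
        cfg = SynthConfig(seed=3, n_areas=2)
        sim = simulate_all(cfg, out_dir=tmp_path)
        pcfg = PrepConfig(start_date=cfg.start_date, end_date=cfg.end_date, strategy="grid")
        panel, _ = prepare_panel(sim["paths"], pcfg)
        for sid in panel.ids():
            if sid.variable != "toxicity":
                continue
            original = sim["toxicity_obs"][sid]
            obs = original.observed_mask
            np.testing.assert_allclose(panel[sid].values[obs], original.values[obs])

    def test_deterministic_panel_hash(self, tmp_path):
        cfg = SynthConfig(seed=4, n_areas=2)
        sim = simulate_all(cfg, out_dir=tmp_path)
        pcfg = PrepConfig(start_date=cfg.start_date, end_date=cfg.end_date,
                          strategy="grid", seed=17)
        a, _ = prepare_panel(sim["paths"], pcfg)
        b, _ = prepare_panel(sim["paths"], pcfg)
        assert a.to_frame().to_csv() == b.to_frame().to_csv()
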
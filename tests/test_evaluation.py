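"""Backtesting protocol: metrics, splits, masks, breakdowns, comparisons."""

import datetime as dt
import math

import numpy as np
import pytest

import surgecast as sc
from surgecast.errors import ValidationError
from surgecast.evaluation import (
    BreakdownBy,
    MaskKind,
    apply_mask,
    breakdown,
    build_error_records,
    chronological_split,
    compare_models,
    error_metrics,
    naive_weekday_forecast,
    percentage_error,
    run_benchmark,
)
from surgecast.io import DailyDemandSeries, slice_series
from surgecast.rolling import RollingWindowConfig


class TestErrorMetrics:
    def test_hand_computed_example(self):
        m = error_metrics([10, 20], [8, 25])
        assert m.mae == pytest.approx(3.5)
        assert m.mse == pytest.approx(14.5)
        assert m.rmse == pytest.approx(math.sqrt(14.5))
        assert m.mape == pytest.approx(22.5)

    def test_perfect_forecast(self):
        m = error_metrics([5, 9, 13], [5, 9, 13])
        assert (m.mae, m.mse, m.rmse, m.mape) == (0, 0, 0, 0)

    def test_over_estimation_gives_negative_pe(self):
        assert percentage_error(13, 21) == pytest.approx(-61.5385, abs=1e-3)

    def test_zero_actual_directs_to_masking(self):
        with pytest.raises(ValidationError, match="mask"):
            error_metrics([0, 5], [1, 5])

    def test_identities_on_random_data(self):
        rng = np.random.default_rng(0)
        y = rng.integers(1, 100, size=200)
        f = y + rng.normal(0, 5, size=200)
        m = error_metrics(y, f)
        assert m.rmse**2 == pytest.approx(m.mse, rel=1e-9)
        assert m.mae <= m.rmse + 1e-12
        scaled = error_metrics(3 * y, 3 * f)
        assert scaled.mape == pytest.approx(m.mape, rel=1e-9)


class TestChronologicalSplit:
    @pytest.fixture()
    def four_years(self):
        n = (dt.date(2019, 12, 31) - dt.date(2016, 1, 1)).days + 1
        return DailyDemandSeries.from_values("overall", dt.date(2016, 1, 1),
                                             np.arange(n) % 9 + 1)

    def test_three_year_split_bounds(self, four_years):
        train, test = chronological_split(four_years, dt.date(2019, 1, 1), 3)
        assert (train.start, train.end) == (dt.date(2016, 1, 1), dt.date(2018, 12, 31))
        assert (test.start, test.end) == (dt.date(2019, 1, 1), dt.date(2019, 12, 31))

    def test_one_year_split(self, four_years):
        train, _ = chronological_split(four_years, dt.date(2019, 1, 1), 1)
        assert (train.start, train.end) == (dt.date(2018, 1, 1), dt.date(2018, 12, 31))

    @pytest.mark.parametrize("years", [1, 2, 3])
    def test_adjacency_no_overlap(self, four_years, years):
        train, test = chronological_split(four_years, dt.date(2019, 1, 1), years)
        assert train.end + dt.timedelta(days=1) == test.start

    def test_insufficient_coverage_names_shortfall(self, four_years):
        with pytest.raises(ValidationError, match="2015-01-01"):
            chronological_split(four_years, dt.date(2019, 1, 1), 4)


class TestMasks:
    @pytest.fixture()
    def toy_week(self):
        # Mon 2019-04-22 .. Sun 2019-04-28; Thursday 25th is a holiday
        return DailyDemandSeries.from_values("elective", dt.date(2019, 4, 22),
                                             [2, 0, 1, 3, 0, 0, 0])

    def test_elective_mask_drops_weekend_and_holiday(self, toy_week, toy_week_holidays):
        week = DailyDemandSeries.from_values("elective", dt.date(2019, 4, 22),
                                             [5, 6, 7, 8, 9, 0, 0])
        kept = apply_mask(week, MaskKind.ELECTIVE, toy_week_holidays)
        assert len(kept) == 4  # 7 - 2 weekend - 1 holiday

    def test_overall_mask_keeps_all_days(self, toy_week_holidays):
        week = DailyDemandSeries.from_values("overall", dt.date(2019, 4, 22),
                                             [5, 6, 7, 8, 9, 3, 2])
        kept = apply_mask(week, MaskKind.EMERGENCY_OR_OVERALL, toy_week_holidays)
        assert len(kept) == 7

    def test_specialty_mask_also_drops_zero_days(self, toy_week):
        kept = apply_mask(toy_week, MaskKind.SPECIALTY, sc.HolidayCalendar.empty())
        assert kept == [dt.date(2019, 4, 22), dt.date(2019, 4, 24), dt.date(2019, 4, 25)]

    def test_residual_zero_days_dropped_with_warning(self, caplog):
        week = DailyDemandSeries.from_values("overall", dt.date(2019, 4, 22),
                                             [5, 0, 7, 8, 9, 3, 2])
        with caplog.at_level("WARNING"):
            kept = apply_mask(week, MaskKind.EMERGENCY_OR_OVERALL)
        assert len(kept) == 6
        assert any("zero-count" in r.message for r in caplog.records)


class TestBreakdown:
    def _records(self, series, forecasts):
        mask = apply_mask(series, MaskKind.EMERGENCY_OR_OVERALL)
        return build_error_records(series, forecasts, mask)

    def test_group_means_recombine_to_overall_mape(self, calibrated_history):
        sub = slice_series(calibrated_history, dt.date(2018, 1, 1), dt.date(2018, 12, 31))
        forecasts = {d: 70.0 for d in sub.dates()}
        recs = self._records(sub, forecasts)
        overall = np.mean([abs(r.pe) for r in recs])
        for by in BreakdownBy:
            table = breakdown(recs, by)
            recombined = float((table["mape"] * table["n"]).sum() / table["n"].sum())
            assert recombined == pytest.approx(overall, abs=1e-9)

    def test_constant_abs_pe_constant_groups(self):
        series = DailyDemandSeries.from_values("overall", dt.date(2019, 1, 7), [10] * 28)
        recs = self._records(series, {d: 9.0 for d in series.dates()})
        table = breakdown(recs, BreakdownBy.DAY_OF_WEEK)
        assert len(table) == 7
        np.testing.assert_allclose(table["mape"], 10.0)


class TestCompareModels:
    def test_identical_lists_not_significant(self):
        res = compare_models({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res[0].t_statistic == 0.0 and not res[0].significant

    def test_fourteen_models_91_pairs(self):
        rng = np.random.default_rng(1)
        data = {f"m{i}": rng.normal(10, 1, size=30).tolist() for i in range(14)}
        res = compare_models(data, alpha=0.05)
        assert len(res) == 91
        assert res[0].k == 91
        assert res[0].adjusted_alpha == 0.05 / 91

    def test_constant_shift_is_significant(self):
        rng = np.random.default_rng(2)
        base = rng.normal(10, 1, size=365)
        res = compare_models({"a": base.tolist(), "b": (base + 50).tolist()}, alpha=0.05)
        # Bonferroni with K up to 1000 would still flag this difference
        assert res[0].p_value < 0.05 / 1000

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="align"):
            compare_models({"a": [1, 2], "b": [1, 2, 3]})


class TestBenchmark:
    def test_table_shape_and_flags(self, calibrated):
        _, holidays, streams = calibrated
        models = {
            "rw": RollingWindowConfig(tau=1, theta=2),
            "naive": lambda train, dates, hol: naive_weekday_forecast(train, dates),
        }
        res = run_benchmark({"overall": streams["overall"]}, models,
                            dt.date(2019, 1, 1), training_years=(1, 2),
                            holidays=holidays)
        assert len(res.table) == 4  # 2 models x 2 lengths x 1 stream
        assert res.table.groupby("training_years")["best_in_column"].sum().eq(1).all()

    def test_perfect_oracle_row_is_zero(self, weekday_only):
        _, _, streams = weekday_only
        overall = streams["overall"]

        def oracle(train, dates, hol):
            return {d: float(overall.count_on(d)) for d in dates}

        res = run_benchmark({"overall": overall}, {"oracle": oracle},
                            dt.date(2019, 1, 1), training_years=(1,))
        assert res.table["mape"].iloc[0] == 0.0

    def test_rolling_window_exact_on_weekday_only_signal(self, weekday_only):
        _, _, streams = weekday_only
        res = run_benchmark(
            {"overall": streams["overall"]},
            {"rw": RollingWindowConfig(tau=2, theta=2)},
            dt.date(2019, 1, 1), training_years=(2,),
        )
        assert res.table["mape"].iloc[0] == 0.0

    def test_benchmark_rerun_identical(self, calibrated, tmp_path):
        _, holidays, streams = calibrated
        models = {"rw": RollingWindowConfig(tau=1, theta=2),
                  "linear": sc.EstimatorSpec("LINEAR")}
        csvs = []
        for i in range(2):
            res = run_benchmark({"overall": streams["overall"]}, models,
                                dt.date(2019, 1, 1), training_years=(1,),
                                holidays=holidays)
            p = tmp_path / f"b{i}.csv"
            res.table.to_csv(p, index=False)
            csvs.append(p.read_bytes())
        assert csvs[0] == csvs[1]

    def test_no_fit_sees_test_period(self, calibrated):
        """Instrumented backtest: every observation source date and every
        regression training date precedes the test-period start."""
        _, holidays, streams = calibrated
        overall = streams["overall"]
        test_start = dt.date(2019, 1, 1)
        seen: list[dt.date] = []

        import surgecast.evaluation as ev
        import surgecast.rolling as rw

        orig_collect = rw.collect_observations
        orig_fit = ev.fit_forecaster

        def spying_collect(series, doi, config, holidays=None):
            obs = orig_collect(series, doi, config, holidays)
            seen.extend(obs.source_dates())
            return obs

        def spying_fit(spec, training, *args, **kwargs):
            seen.extend([training.start, training.end])
            return orig_fit(spec, training, *args, **kwargs)

        rw.forecast_range.__globals__["collect_observations"] = spying_collect
        ev.run_benchmark.__globals__["fit_forecaster"] = spying_fit
        try:
            run_benchmark(
                {"overall": overall},
                {"rw": RollingWindowConfig(tau=2, theta=2),
                 "linear": sc.EstimatorSpec("LINEAR"),
                 "gb": sc.EstimatorSpec("GRADIENT_BOOSTING")},
                test_start, training_years=(2,), holidays=holidays,
            )
        finally:
            rw.forecast_range.__globals__["collect_observations"] = orig_collect
            ev.run_benchmark.__globals__["fit_forecaster"] = orig_fit
        assert seen and max(seen) < test_start
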
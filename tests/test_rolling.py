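"""Rolling-window forecaster: collection law, aggregation, intervals, horizon."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import surgecast as sc
from surgecast.errors import InsufficientHistoryError, ValidationError
from surgecast.io import DailyDemandSeries, slice_series
from surgecast.rolling import (
    Aggregation,
    HolidayMode,
    Observation,
    ObservationSet,
    Rounding,
    RollingWindowConfig,
    collect_observations,
    forecast_range,
    predict_interval,
    predict_point,
)


def _constant_series(start, days, value=10) -> DailyDemandSeries:
    return DailyDemandSeries.from_values("overall", start, [value] * days)


def _obs(counts) -> ObservationSet:
    doi = dt.date(2019, 6, 14)
    items = [
        Observation(doi - dt.timedelta(days=364 + 7 * i), int(c), 1)
        for i, c in enumerate(counts)
    ]
    return ObservationSet(doi, items)


class TestCollection:
    @pytest.mark.parametrize(
        "tau, theta, expected",
        [(2, 2, 12), (1, 0, 1), (1, 2, 7), (3, 0, 3), (2, 1, 7)],
    )
    def test_observation_count_law(self, tau, theta, expected):
        series = _constant_series(dt.date(2015, 1, 1), 365 * 5)
        cfg = RollingWindowConfig(tau=tau, theta=theta)
        obs = collect_observations(series, dt.date(2019, 6, 14), cfg)
        assert len(obs) == expected == theta + tau * (2 * theta + 1)
        assert obs.coverage == 1.0

    @given(
        st.dates(min_value=dt.date(2019, 1, 1), max_value=dt.date(2019, 12, 31)),
        st.integers(min_value=0, max_value=3),
        st.integers(min_value=1, max_value=3),
    )
    def test_collection_invariants_over_random_dois(self, doi, theta, tau):
        series = _constant_series(dt.date(2015, 1, 1), 365 * 5)
        cfg = RollingWindowConfig(tau=tau, theta=theta)
        obs = collect_observations(series, doi, cfg)
        assert len(obs) == theta + tau * (2 * theta + 1)
        assert all(o.date.weekday() == doi.weekday() for o in obs.items)
        assert all(o.date < doi for o in obs.items)

    def test_doi_not_after_start_rejected(self):
        series = _constant_series(dt.date(2019, 1, 1), 30)
        with pytest.raises(InsufficientHistoryError):
            collect_observations(series, dt.date(2019, 1, 1), RollingWindowConfig())

    def test_partial_coverage_skips_and_reports(self):
        # only ~1.5 years of history but tau=3 requested
        series = _constant_series(dt.date(2017, 8, 1), 520)
        cfg = RollingWindowConfig(tau=3, theta=2)
        obs = collect_observations(series, dt.date(2019, 1, 2), cfg)
        assert 0 < len(obs) < 2 + 3 * 5
        assert obs.n_missing == obs.n_requested - len(obs)
        assert obs.coverage < 1.0

    def test_holiday_aware_drops_holiday_sources_for_plain_doi(self):
        series = _constant_series(dt.date(2016, 1, 1), 365 * 4)
        doi = dt.date(2019, 4, 18)  # Thursday
        holiday = dt.date(2018, 4, 19)  # a Thursday in last year's window
        cal = sc.HolidayCalendar.from_dates([holiday])
        cfg = RollingWindowConfig(tau=1, theta=2, holiday_mode=HolidayMode.HOLIDAY_AWARE)
        obs = collect_observations(series, doi, cfg, cal)
        assert holiday not in obs.source_dates()
        plain = collect_observations(series, doi, cfg.with_(holiday_mode=HolidayMode.CALENDAR_ONLY), cal)
        assert holiday in plain.source_dates()

    def test_holiday_aware_doi_on_holiday_uses_offdays(self):
        series = _constant_series(dt.date(2016, 1, 1), 365 * 4)
        holidays = sc.synthetic_holidays(range(2016, 2020))
        doi = dt.date(2019, 4, 25)  # a synthetic-calendar holiday (Thursday)
        cfg = RollingWindowConfig(tau=3, theta=2, holiday_mode=HolidayMode.HOLIDAY_AWARE)
        obs = collect_observations(series, doi, cfg, holidays)
        assert len(obs) >= 3
        for o in obs.items:
            t = sc.day_type(o.date, holidays)
            assert t is sc.DayType.PUBLIC_HOLIDAY or t.is_weekend


class TestPointPrediction:
    def test_uniform_mean(self):
        assert predict_point(_obs([12, 18, 24]), RollingWindowConfig()) == 18.0

    def test_singleton_any_aggregation(self):
        for agg in Aggregation:
            cfg = RollingWindowConfig(aggregation=agg)
            assert predict_point(_obs([21]), cfg) == 21

    def test_rounded_mean_matches_reported_integer_prediction(self):
        # a mean of historic counts between 12 and 24 reported as the integer 18
        cfg = RollingWindowConfig(rounding=Rounding.NEAREST_INT)
        assert predict_point(_obs([12, 13, 24, 23]), cfg) == 18

    def test_round_half_away_from_zero(self):
        cfg = RollingWindowConfig(rounding=Rounding.NEAREST_INT)
        assert predict_point(_obs([12, 13]), cfg) == 13  # 12.5 -> 13

    @given(st.lists(st.integers(min_value=0, max_value=120), min_size=1, max_size=30))
    def test_aggregation_bounds(self, counts):
        obs = _obs(counts)
        lo = predict_point(obs, RollingWindowConfig(aggregation=Aggregation.MIN))
        mid = predict_point(obs, RollingWindowConfig(aggregation=Aggregation.UNIFORM_MEAN))
        hi = predict_point(obs, RollingWindowConfig(aggregation=Aggregation.MAX))
        assert lo <= mid <= hi

    def test_per_year_mean_differs_from_pooled_on_unbalanced_years(self):
        doi = dt.date(2019, 6, 14)
        items = [
            Observation(doi - dt.timedelta(days=7), 10, 0),
            Observation(doi - dt.timedelta(days=364), 20, 1),
            Observation(doi - dt.timedelta(days=371), 30, 1),
        ]
        obs = ObservationSet(doi, items)
        pooled = predict_point(obs, RollingWindowConfig())
        per_year = predict_point(
            obs, RollingWindowConfig(aggregation=Aggregation.PER_YEAR_MEAN)
        )
        assert pooled == pytest.approx(20.0)
        assert per_year == pytest.approx((10 + 25) / 2)

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientHistoryError):
            predict_point(ObservationSet(dt.date(2019, 1, 1), []), RollingWindowConfig())


class TestIntervals:
    def test_zero_variance_degenerate(self):
        f = predict_interval(_obs([7, 7, 7]), RollingWindowConfig())
        assert f.lower == f.point == f.upper == 7.0

    def test_t_interval_matches_closed_form(self):
        f = predict_interval(_obs([12, 18, 24]), RollingWindowConfig(level=0.95))
        s = 6.0
        half = stats.t.ppf(0.975, df=2) * s * math.sqrt(1 + 1 / 3)
        assert f.point == pytest.approx(18.0)
        assert f.lower == pytest.approx(max(0.0, 18 - half))
        assert f.upper == pytest.approx(18 + half)

    def test_lower_clipped_at_zero(self):
        f = predict_interval(_obs([1, 2, 30]), RollingWindowConfig(level=0.99))
        assert f.lower == 0.0

    def test_wider_level_never_narrows(self):
        narrow = predict_interval(_obs([12, 18, 24]), RollingWindowConfig(level=0.80))
        wide = predict_interval(_obs([12, 18, 24]), RollingWindowConfig(level=0.95))
        assert wide.upper - wide.lower >= narrow.upper - narrow.lower

    def test_singleton_degenerate(self):
        f = predict_interval(_obs([21]), RollingWindowConfig())
        assert (f.lower, f.point, f.upper) == (21.0, 21.0, 21.0)


class TestForecastRange:
    def test_horizon_length_and_leakage_guard(self, weekday_only):
        _, _, streams = weekday_only
        overall = streams["overall"]
        history = slice_series(overall, dt.date(2016, 1, 1), dt.date(2018, 12, 31))
        fcs = forecast_range(
            history, dt.date(2019, 1, 1), dt.date(2019, 12, 31), RollingWindowConfig(tau=3)
        )
        assert len(fcs) == 365
        with pytest.raises(ValidationError, match="history must end before"):
            forecast_range(
                overall, dt.date(2019, 1, 1), dt.date(2019, 1, 5), RollingWindowConfig()
            )

    def test_single_day_horizon(self):
        series = _constant_series(dt.date(2018, 1, 1), 400)
        fcs = forecast_range(
            series, dt.date(2019, 3, 1), dt.date(2019, 3, 1), RollingWindowConfig()
        )
        assert len(fcs) == 1

    def test_exact_on_pure_weekday_signal(self, weekday_only):
        params, _, streams = weekday_only
        overall = streams["overall"]
        history = slice_series(overall, dt.date(2016, 1, 1), dt.date(2018, 12, 31))
        fcs = forecast_range(
            history, dt.date(2019, 1, 1), dt.date(2019, 12, 31),
            RollingWindowConfig(tau=2, theta=2),
        )
        for f in fcs:
            assert f.point == overall.count_on(f.date)

    def test_deterministic_repeat(self, calibrated_history):
        cfg = RollingWindowConfig(tau=2, theta=2)
        a = forecast_range(calibrated_history, dt.date(2019, 1, 1), dt.date(2019, 1, 31), cfg)
        b = forecast_range(calibrated_history, dt.date(2019, 1, 1), dt.date(2019, 1, 31), cfg)
        assert a == b

    def test_no_source_date_reaches_horizon(self, calibrated_history):
        start = dt.date(2019, 1, 1)
        cfg = RollingWindowConfig(tau=3, theta=3)
        d = start
        while d <= dt.date(2019, 12, 31):
            obs = collect_observations(calibrated_history, d, cfg)
            assert max(obs.source_dates()) < start
            d += dt.timedelta(days=17)
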
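"""Photo-degree-day features and weather-window assembly."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikecast.errors import ValidationError
from spikecast.weather import (
    CONDITION_FACTORS,
    DailyWeather,
    MonthlyClimatology,
    WindowStats,
    build_weather_window,
    compute_cpdd,
    compute_pdd,
    denormalize_window,
    estimate_forecast_sunlight,
    normalize_window,
)

CLIM = MonthlyClimatology({m: 8.0 for m in range(1, 13)})


def make_series(start, n, tmin=5.0, tmax=15.0, sunlight=8.0, rain=0.0,
                condition="mostly_sunny"):
    return [
        DailyWeather(
            date=start + dt.timedelta(days=k),
            tmin=tmin, tmax=tmax, sunlight=sunlight, rainfall=rain,
            condition=condition,
        )
        for k in range(n)
    ]


class TestPDD:
    @pytest.mark.parametrize(
        "tmax,tmin,sun,expected",
        [(20, 10, 0, 0.0), (15, 15, 9, 0.0), (20, 10, 8, 40.0)],
    )
    def test_examples(self, tmax, tmin, sun, expected):
        assert compute_pdd(tmax, tmin, sun) == pytest.approx(expected)

    def test_rejects_inverted_temperatures_naming_field(self):
        with pytest.raises(ValidationError, match="tmax"):
            compute_pdd(5, 10, 4)

    def test_rejects_negative_sunlight_naming_field(self):
        with pytest.raises(ValidationError, match="sunlight"):
            compute_pdd(20, 10, -1)

    @given(
        tmin=st.floats(-20, 30),
        trange=st.floats(0, 30),
        sun=st.floats(0, 24),
    )
    @settings(max_examples=200, deadline=None)
    def test_nonnegative_and_linear_in_sunlight(self, tmin, trange, sun):
        pdd = compute_pdd(tmin + trange, tmin, sun)
        assert pdd >= 0
        assert compute_pdd(tmin + trange, tmin, 2 * sun) == pytest.approx(
            2 * pdd, abs=1e-9
        )


class TestCPDD:
    @pytest.mark.parametrize(
        "series,expected",
        [([5], [5]), ([0, 0, 0], [0, 0, 0]), ([10, 20, 5], [10, 30, 35])],
    )
    def test_examples(self, series, expected):
        assert compute_cpdd(series).tolist() == expected

    def test_empty_series_rejected(self):
        with pytest.raises(ValidationError):
            compute_cpdd([])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_nondecreasing_and_first_difference_recovers_pdd(self, series):
        cpdd = compute_cpdd(series)
        assert np.all(np.diff(cpdd) >= -1e-9)
        recovered = np.diff(np.concatenate([[0.0], cpdd]))
        assert np.allclose(recovered, series, atol=1e-6)


class TestForecastSunlight:
    def test_factors_are_the_five_published_fractions(self):
        assert CONDITION_FACTORS == {
            "sunny": 1.00, "mostly_sunny": 0.75, "mostly_cloudy": 0.50,
            "cloudy": 0.25, "shower": 0.00,
        }

    @pytest.mark.parametrize(
        "condition,mean,expected",
        [("shower", 8.0, 0.0), ("sunny", 10.0, 10.0), ("mostly_sunny", 8.0, 6.0)],
    )
    def test_examples(self, condition, mean, expected):
        clim = MonthlyClimatology({m: mean for m in range(1, 13)})
        assert estimate_forecast_sunlight(condition, 6, clim) == pytest.approx(expected)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValidationError):
            estimate_forecast_sunlight("hail", 6, CLIM)

    def test_monotone_in_category_factor(self):
        order = ["shower", "cloudy", "mostly_cloudy", "mostly_sunny", "sunny"]
        values = [estimate_forecast_sunlight(c, 3, CLIM) for c in order]
        assert values == sorted(values)


class TestBuildWindow:
    def test_default_window_has_97_rows_imaging_at_row_90(self):
        imaging = dt.date(2023, 9, 1)
        series = make_series(imaging - dt.timedelta(days=90), 97)
        window = build_weather_window(series, imaging, CLIM)
        assert window.matrix.shape == (97, 6)
        assert window.imaging_row_index == 90
        assert window.imaging_date == imaging

    def test_single_row_window_cpdd_equals_pdd(self):
        imaging = dt.date(2023, 9, 1)
        series = make_series(imaging, 1)
        window = build_weather_window(series, imaging, CLIM,
                                      history_days=0, forecast_days=0)
        assert window.matrix.shape == (1, 6)
        assert window.matrix[0, 5] == pytest.approx(window.matrix[0, 4])

    def test_zero_sunlight_gives_zero_pdd_and_cpdd(self):
        imaging = dt.date(2023, 9, 1)
        series = make_series(imaging - dt.timedelta(days=5), 9,
                             sunlight=0.0, condition="shower")
        window = build_weather_window(series, imaging, CLIM,
                                      history_days=5, forecast_days=3)
        assert np.all(window.matrix[:, 4] == 0)
        assert np.all(window.matrix[:, 5] == 0)

    def test_forecast_rows_use_condition_based_sunlight(self):
        imaging = dt.date(2023, 9, 1)
        series = make_series(imaging - dt.timedelta(days=2), 5,
                             sunlight=9.0, condition="cloudy")
        window = build_weather_window(series, imaging, CLIM,
                                      history_days=2, forecast_days=2)
        # history + imaging day keep the measured 9 h
        assert np.all(window.matrix[:3, 2] == 9.0)
        # forecast days: 25 % of the 8 h monthly mean
        assert np.all(window.matrix[3:, 2] == 2.0)

    def test_missing_interior_day_rejected_with_gap(self):
        imaging = dt.date(2023, 9, 1)
        series = make_series(imaging - dt.timedelta(days=5), 9)
        del series[2]
        with pytest.raises(ValidationError, match="missing"):
            build_weather_window(series, imaging, CLIM,
                                 history_days=5, forecast_days=3)

    def test_duplicate_dates_rejected(self):
        imaging = dt.date(2023, 9, 1)
        series = make_series(imaging - dt.timedelta(days=3), 5)
        series.append(series[0])
        with pytest.raises(ValidationError, match="duplicate"):
            build_weather_window(series, imaging, CLIM,
                                 history_days=3, forecast_days=1)

    def test_deterministic_bit_identical(self):
        imaging = dt.date(2023, 9, 1)
        series = make_series(imaging - dt.timedelta(days=10), 14)
        w1 = build_weather_window(series, imaging, CLIM, 10, 3)
        w2 = build_weather_window(series, imaging, CLIM, 10, 3)
        assert w1.matrix.tobytes() == w2.matrix.tobytes()

    def test_cpdd_column_is_running_sum_of_pdd_column(self):
        imaging = dt.date(2023, 9, 1)
        rng = np.random.default_rng(3)
        series = [
            DailyWeather(
                date=imaging - dt.timedelta(days=10) + dt.timedelta(days=k),
                tmin=float(t), tmax=float(t + r), sunlight=float(s),
                rainfall=0.0, condition="sunny",
            )
            for k, (t, r, s) in enumerate(
                zip(rng.uniform(0, 15, 14), rng.uniform(0, 10, 14),
                    rng.uniform(0, 12, 14))
            )
        ]
        window = build_weather_window(series, imaging, CLIM, 10, 3)
        assert np.allclose(window.matrix[:, 5], np.cumsum(window.matrix[:, 4]))


class TestNormalize:
    def test_window_equal_to_means_maps_to_zero(self):
        stats = WindowStats(mean=np.arange(6.0), sd=np.ones(6))
        mat = np.tile(np.arange(6.0), (5, 1))
        assert np.all(normalize_window(mat, stats) == 0)

    def test_constant_column_maps_to_zero_without_error(self):
        mats = [np.column_stack([np.ones(4), np.arange(4.0)] + [np.ones(4)] * 4)]
        stats = WindowStats.fit(mats)
        out = normalize_window(mats[0], stats)
        assert np.all(out[:, 0] == 0)
        assert np.isfinite(out).all()

    def test_round_trip_when_all_sd_positive(self):
        rng = np.random.default_rng(0)
        mats = [rng.normal(size=(7, 6)) for _ in range(3)]
        stats = WindowStats.fit(mats)
        back = denormalize_window(normalize_window(mats[0], stats), stats)
        assert np.allclose(back, mats[0], atol=1e-9)

    def test_column_mismatch_rejected(self):
        stats = WindowStats(mean=np.zeros(4), sd=np.ones(4))
        with pytest.raises(ValidationError):
            normalize_window(np.zeros((3, 6)), stats)


def test_daily_weather_invariants():
    with pytest.raises(ValidationError):
        DailyWeather(dt.date(2023, 1, 1), tmin=10, tmax=5, sunlight=5, rainfall=0)
    with pytest.raises(ValidationError):
        DailyWeather(dt.date(2023, 1, 1), tmin=0, tmax=5, sunlight=30, rainfall=0)
    # a forecast day without measured sunlight must carry a condition
    with pytest.raises(ValidationError):
        DailyWeather(dt.date(2023, 1, 1), tmin=0, tmax=5, sunlight=None,
                     rainfall=0, condition="none", is_forecast=True)
    ok = DailyWeather(dt.date(2023, 1, 1), tmin=0, tmax=5, sunlight=None,
                      rainfall=0, condition="cloudy", is_forecast=True)
    assert ok.sunlight is None


def test_climatology_requires_all_months_in_range():
    with pytest.raises(ValidationError):
        MonthlyClimatology({m: 8.0 for m in range(1, 12)})
    with pytest.raises(ValidationError):
        MonthlyClimatology({**{m: 8.0 for m in range(1, 13)}, 6: 25.0})
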
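"""Synthetic world: weather realism constraints, threshold phenology,
procedural head rendering, and dataset emission round-trips."""

import datetime as dt

import numpy as np
import pytest

from spikecast.errors import ValidationError
from spikecast.simulate import (
    SimConfig,
    SimPlant,
    assign_phenology,
    build_dataset,
    emit_dataset,
    head_pixel_count,
    make_climatology,
    make_plants,
    render_head_image,
    simulate_weather,
)

START = dt.date(2023, 4, 1)

TINY = dict(
    n_plants=4,
    sowing_dates=(dt.date(2023, 4, 27),),
    images_per_day=2,
    obs_days_to_anthesis=(4, 6),
    image_size=16,
)


class TestWeather:
    def test_same_seed_gives_identical_series(self):
        cfg = SimConfig()
        a = simulate_weather(cfg, START, 50, seed=3)
        b = simulate_weather(cfg, START, 50, seed=3)
        assert all(
            (x.tmin, x.tmax, x.sunlight, x.rainfall, x.condition)
            == (y.tmin, y.tmax, y.sunlight, y.rainfall, y.condition)
            for x, y in zip(a, b)
        )

    def test_tmax_never_below_tmin_over_long_horizon(self):
        series = simulate_weather(SimConfig(), START, 10000, seed=1)
        assert all(rec.tmax >= rec.tmin for rec in series)
        assert all(0 <= rec.sunlight <= 24 for rec in series)
        assert all(rec.rainfall >= 0 for rec in series)

    def test_zero_noise_zero_amplitude_yields_constant_means(self):
        cfg = SimConfig(
            tmin_amp=0.0, temp_noise_sd=0.0, sunlight_amp=0.0,
            sunlight_noise_sd=0.0, rain_prob=0.0,
        )
        series = simulate_weather(cfg, START, 30, seed=0)
        assert all(rec.tmin == pytest.approx(cfg.tmin_mean) for rec in series)
        assert all(
            rec.tmax == pytest.approx(cfg.tmin_mean + cfg.trange_mean)
            for rec in series
        )
        assert all(rec.sunlight == pytest.approx(cfg.sunlight_mean) for rec in series)
        assert all(rec.rainfall == 0.0 for rec in series)

    def test_climatology_covers_all_months(self):
        clim = make_climatology(SimConfig())
        assert all(0 < clim[m] < 24 for m in range(1, 13))


class TestPhenology:
    def test_zero_dispersion_flowers_one_day_per_group(self):
        cfg = SimConfig(sigma_theta=0.0, n_plants=20)
        weather = simulate_weather(cfg, START, 250, seed=0)
        plants = make_plants(cfg, seed=0)
        assign_phenology(plants, weather, cfg)
        for g in (0, 1):
            dates = {p.anthesis_date for p in plants if p.sowing_group == g}
            assert len(dates) == 1

    def test_more_sunlight_never_delays_anthesis(self):
        cfg = SimConfig(n_plants=20)
        weather = simulate_weather(cfg, START, 250, seed=2)
        doubled = [
            type(rec)(
                date=rec.date, tmin=rec.tmin, tmax=rec.tmax,
                sunlight=min(24.0, 2 * rec.sunlight), rainfall=rec.rainfall,
                condition=rec.condition,
            )
            for rec in weather
        ]
        base = assign_phenology(make_plants(cfg, seed=2), weather, cfg)
        fast = assign_phenology(make_plants(cfg, seed=2), doubled, cfg)
        for p_base, p_fast in zip(base, fast):
            assert p_fast.anthesis_date <= p_base.anthesis_date

    def test_later_warmer_sowing_group_develops_faster(self):
        ds = build_dataset(SimConfig())
        dur = {g: [] for g in (0, 1)}
        for p in ds.plants:
            dur[p.sowing_group].append((p.anthesis_date - p.sowing_date).days)
        assert np.mean(dur[1]) < np.mean(dur[0])

    def test_unreachable_threshold_raises_with_advice(self):
        cfg = SimConfig(theta0=1e9, n_plants=2)
        weather = simulate_weather(cfg, START, 100, seed=0)
        with pytest.raises(ValidationError, match="extend"):
            assign_phenology(make_plants(cfg, seed=0), weather, cfg)

    def test_thresholds_truncated_positive(self):
        cfg = SimConfig(theta0=100.0, sigma_theta=500.0, n_plants=50)
        plants = make_plants(cfg, seed=0)
        assert all(p.theta > 0 for p in plants)


class TestRendering:
    def test_fully_booted_head_shows_fewer_head_pixels_than_exposed(self):
        lo = head_pixel_count(render_head_image(0.0, 5))
        hi = head_pixel_count(render_head_image(1.0, 5))
        assert lo < hi

    def test_head_pixel_count_monotone_in_progress_at_fixed_nuisance(self):
        counts = [
            head_pixel_count(render_head_image(p, 11))
            for p in np.linspace(0.0, 1.0, 8)
        ]
        assert all(a < b for a, b in zip(counts, counts[1:]))

    def test_deterministic_per_nuisance_seed(self):
        assert np.array_equal(render_head_image(0.5, 9), render_head_image(0.5, 9))

    def test_progress_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            render_head_image(1.5, 0)


class TestDatasetBuild:
    def test_counting_plants_days_images(self):
        ds = build_dataset(SimConfig(**TINY))
        # 4 plants x 3 observation days x 2 images
        assert len(ds.pool) == 4 * 3 * 2
        manifest_rows = {(i.plant_id, i.capture_date, i.image.source_id)
                         for i in ds.pool}
        assert len(manifest_rows) == len(ds.pool)

    def test_days_to_anthesis_consistent_with_ground_truth(self):
        ds = build_dataset(SimConfig(**TINY))
        anthesis = {p.plant_id: p.anthesis_date for p in ds.plants}
        for iwc in ds.pool:
            assert iwc.days_to_anthesis >= 0
            assert (anthesis[iwc.plant_id] - iwc.capture_date).days == (
                iwc.days_to_anthesis
            )

    def test_windows_share_objects_across_plants_same_day(self):
        ds = build_dataset(SimConfig(**TINY))
        by_date = {}
        for iwc in ds.pool:
            by_date.setdefault(iwc.capture_date, set()).add(id(iwc.weather))
        assert all(len(v) == 1 for v in by_date.values())

    def test_plant_seed_changes_plants_not_weather(self):
        cfg = SimConfig(**TINY)
        a = build_dataset(cfg)
        b = build_dataset(cfg, plant_seed=99)
        assert [r.tmin for r in a.weather] == [r.tmin for r in b.weather]
        assert any(
            pa.theta != pb.theta for pa, pb in zip(a.plants, b.plants)
        )


class TestEmission:
    def test_regeneration_is_byte_identical(self, tmp_path):
        cfg = SimConfig(**TINY)
        d1 = emit_dataset(cfg, tmp_path / "a")
        d2 = emit_dataset(cfg, tmp_path / "b")
        for name in ("manifest.csv", "weather.csv", "climatology.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_round_trip_through_module_readers(self, tmp_path):
        from spikecast.io import load_pool

        cfg = SimConfig(**TINY, history_days=20, forecast_days=3)
        out = emit_dataset(cfg, tmp_path / "ds")
        ds = build_dataset(cfg)
        pool = load_pool(out, history_days=20, forecast_days=3)
        assert len(pool) == len(ds.pool)
        by_src = {i.image.source_id: i for i in ds.pool}
        for iwc in pool:
            src = iwc.image.source_id.split("/")[-1].removesuffix(".png")
            orig = by_src[src]
            assert np.array_equal(iwc.image.pixels, orig.image.pixels)
            assert iwc.days_to_anthesis == orig.days_to_anthesis
            assert np.allclose(iwc.weather.matrix, orig.weather.matrix)
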
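"""Self-contained synthetic benchmark: weather, phenology, head images.

The simulated world is deliberately governed by exactly the quantities
the model consumes.  A southern-hemisphere season produces daily
weather; each plant i draws an individual flowering threshold
theta_i ~ Normal(theta0, sigma_theta^2) (truncated positive) expressing
micro-environmental variation, and flowers on the first day its
cumulative photo-degree days since sowing reach theta_i.  Head
appearance encodes developmental progress: the rendered head's exposed
fraction grows with the plant's accumulated CPDD relative to its own
threshold.  Because theta_i is latent, the image alone under-determines
days-to-anthesis when sigma_theta is large; combining image progress
with the weather window (which reveals the accumulation rate) resolves
it — the same micro/macro-environment split the method assumes in the
field.

Image realism is deliberately low (procedural shapes); the contract is
a monotone appearance-vs-progress relationship, which is the signal the
method exploits.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset import IWC
from .errors import ValidationError
from .imageprep import HeadImage
from .weather import (
    DailyWeather,
    MonthlyClimatology,
    WeatherWindow,
    build_weather_window,
    compute_pdd,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark."""

    n_plants: int = 120
    sowing_dates: tuple = (dt.date(2023, 4, 27), dt.date(2023, 5, 21))
    # weather seasonality (southern hemisphere: coldest/darkest mid-year)
    tmin_mean: float = 7.0
    tmin_amp: float = 3.0
    trange_mean: float = 9.0
    temp_noise_sd: float = 1.5
    sunlight_mean: float = 7.0
    sunlight_amp: float = 2.5
    sunlight_noise_sd: float = 1.0
    rain_prob: float = 0.3
    rain_scale: float = 3.0
    # phenology: CPDD flowering threshold and its per-plant dispersion.
    # sigma_theta ~ 120 degree-hours corresponds to roughly a +/-4 day
    # flowering spread within a sowing group, matching the 5-10 day
    # within-field variability reported for wheat trials.
    theta0: float = 2600.0
    sigma_theta: float = 120.0
    emergence_start_frac: float = 0.80
    # imaging
    image_size: int = 32
    image_noise_sd: float = 0.04
    blur_max_passes: int = 2
    images_per_day: int = 6
    obs_days_to_anthesis: tuple = (3, 18)
    history_days: int = 90
    forecast_days: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_plants < 2:
            raise ValidationError("n_plants must be >= 2")
        if self.sigma_theta < 0:
            raise ValidationError("sigma_theta must be >= 0")
        if self.theta0 <= 0:
            raise ValidationError("theta0 must be > 0")
        if not self.sowing_dates:
            raise ValidationError("need at least one sowing group")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        """Build from a plain dict (e.g. parsed YAML): ISO date strings
        and lists are coerced to the native field types."""
        kwargs = dict(mapping)
        if "sowing_dates" in kwargs:
            kwargs["sowing_dates"] = tuple(
                d if isinstance(d, dt.date) else dt.date.fromisoformat(str(d))
                for d in kwargs["sowing_dates"]
            )
        if "obs_days_to_anthesis" in kwargs:
            kwargs["obs_days_to_anthesis"] = tuple(
                int(x) for x in kwargs["obs_days_to_anthesis"]
            )
        return cls(**kwargs)

    @classmethod
    def weather_dominated(cls, **overrides) -> "SimConfig":
        """Variant with large threshold dispersion: appearance alone
        under-determines days-to-anthesis, so the weather channel
        carries indispensable signal."""
        kwargs = dict(sigma_theta=320.0)
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SimPlant:
    plant_id: str
    sowing_group: int
    sowing_date: dt.date
    theta: float
    anthesis_date: dt.date | None = None


def seasonal_sunlight(doy: np.ndarray | float, config: SimConfig) -> np.ndarray:
    """Noise-free seasonal sunlight curve (minimum near the June solstice)."""
    return config.sunlight_mean - config.sunlight_amp * np.cos(
        2.0 * np.pi * (np.asarray(doy, dtype=float) - 172.0) / 365.25
    )


def make_climatology(config: SimConfig) -> MonthlyClimatology:
    """Monthly means of the seasonal sunlight curve (the '20-year normal')."""
    by_month: dict[int, list[float]] = {m: [] for m in range(1, 13)}
    day = dt.date(2023, 1, 1)
    while day.year == 2023:
        by_month[day.month].append(
            float(seasonal_sunlight(day.timetuple().tm_yday, config))
        )
        day += dt.timedelta(days=1)
    means = {
        m: float(np.clip(np.mean(v), 0.01, 23.99)) for m, v in by_month.items()
    }
    return MonthlyClimatology(means)


def _condition_for(sunlight: float, monthly_mean: float) -> str:
    ratio = sunlight / monthly_mean if monthly_mean > 0 else 0.0
    if ratio >= 0.875:
        return "sunny"
    if ratio >= 0.625:
        return "mostly_sunny"
    if ratio >= 0.375:
        return "mostly_cloudy"
    if ratio >= 0.125:
        return "cloudy"
    return "shower"


def simulate_weather(
    config: SimConfig, start_date: dt.date, n_days: int, seed: int | None = None
) -> list[DailyWeather]:
    """Daily weather series: seasonal sinusoids + noise, deterministic per seed."""
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    rng = np.random.Generator(np.random.PCG64(config.seed if seed is None else seed))
    clim = make_climatology(config)
    records = []
    for k in range(n_days):
        date = start_date + dt.timedelta(days=k)
        doy = date.timetuple().tm_yday
        tmin = (
            config.tmin_mean
            - config.tmin_amp * np.cos(2.0 * np.pi * (doy - 195.0) / 365.25)
            + rng.normal(0.0, config.temp_noise_sd)
        )
        trange = abs(rng.normal(config.trange_mean, config.temp_noise_sd))
        sun = float(
            np.clip(
                seasonal_sunlight(doy, config)
                + rng.normal(0.0, config.sunlight_noise_sd),
                0.0,
                24.0,
            )
        )
        rain = float(rng.exponential(config.rain_scale)) if rng.random() < config.rain_prob else 0.0
        records.append(
            DailyWeather(
                date=date,
                tmin=float(tmin),
                tmax=float(tmin + trange),
                sunlight=sun,
                rainfall=rain,
                condition=_condition_for(sun, clim[date.month]),
                is_forecast=False,
            )
        )
    return records


def _cpdd_since(records: list[DailyWeather], start: dt.date) -> dict[dt.date, float]:
    """Cumulative PDD from ``start`` (inclusive) for every later date."""
    acc = 0.0
    out = {}
    for rec in records:
        if rec.date < start:
            continue
        acc += compute_pdd(rec.tmax, rec.tmin, rec.sunlight)
        out[rec.date] = acc
    return out


def assign_phenology(
    plants: list[SimPlant], weather: list[DailyWeather], config: SimConfig
) -> list[SimPlant]:
    """Set each plant's anthesis date from its CPDD threshold."""
    cum_by_group = {
        g: _cpdd_since(weather, d) for g, d in enumerate(config.sowing_dates)
    }
    for plant in plants:
        cum = cum_by_group[plant.sowing_group]
        anthesis = None
        for date in sorted(cum):
            if cum[date] >= plant.theta:
                anthesis = date
                break
        if anthesis is None:
            raise ValidationError(
                f"plant {plant.plant_id} never reaches its threshold "
                f"{plant.theta:.0f} within the simulated window; extend it"
            )
        plant.anthesis_date = anthesis
    return plants


def make_plants(config: SimConfig, seed: int | None = None) -> list[SimPlant]:
    rng = np.random.Generator(np.random.PCG64((config.seed if seed is None else seed) + 1))
    plants = []
    n_groups = len(config.sowing_dates)
    for i in range(config.n_plants):
        group = i % n_groups
        theta = rng.normal(config.theta0, config.sigma_theta)
        while theta <= 0:  # truncate the threshold distribution at zero
            theta = rng.normal(config.theta0, config.sigma_theta)
        plants.append(
            SimPlant(
                plant_id=f"g{group}_p{i:04d}",
                sowing_group=group,
                sowing_date=config.sowing_dates[group],
                theta=float(theta),
            )
        )
    return plants


def _box_blur(img: np.ndarray, passes: int) -> np.ndarray:
    for _ in range(passes):
        padded = np.pad(img, ((1, 1), (1, 1), (0, 0)), mode="edge")
        img = (
            padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2]
            + padded[1:-1, 2:] + padded[1:-1, 1:-1]
        ) / 5.0
    return img


def render_head_image(
    progress: float,
    nuisance_seed: int,
    size: int = 32,
    noise_sd: float = 0.04,
    blur_max_passes: int = 2,
) -> np.ndarray:
    """Procedural head crop: exposed head fraction equals ``progress``.

    A textured background, a dark-green sheath, and a golden head
    ellipse whose portion above the sheath collar equals ``progress``;
    nuisances (rotation up to +/-15 degrees, illumination gain, noise,
    blur) are drawn from ``nuisance_seed``.
    """
    if not (0.0 <= progress <= 1.0):
        raise ValidationError("progress must be in [0, 1]")
    rng = np.random.Generator(np.random.PCG64(nuisance_seed))
    angle = np.deg2rad(rng.uniform(-15.0, 15.0))
    gain = rng.uniform(0.8, 1.2)
    passes = int(rng.integers(0, blur_max_passes + 1))

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cx = cy = (size - 1) / 2.0
    # rotate the coordinate frame (scene rotation)
    xr = (xx - cx) * np.cos(angle) - (yy - cy) * np.sin(angle)
    yr = (xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)

    # background: green-brown base + smooth noise texture
    coarse = rng.normal(0.0, 1.0, size=(size // 4 + 2, size // 4 + 2))
    texture = np.kron(coarse, np.ones((4, 4)))[:size, :size]
    img = np.empty((size, size, 3))
    img[..., 0] = 0.25 + 0.05 * texture
    img[..., 1] = 0.35 + 0.06 * texture
    img[..., 2] = 0.16 + 0.04 * texture

    # geometry in the rotated frame (units of image size)
    sheath_top = 0.05 * size          # collar height above centre
    head_h = 0.45 * size
    head_w = 0.14 * size
    # head centre position: fully hidden at progress 0, fully out at 1
    head_cy = sheath_top + head_h / 2.0 - progress * head_h
    head_mask = (
        (xr / head_w) ** 2 + ((yr - head_cy) / (head_h / 2.0)) ** 2
    ) <= 1.0
    img[head_mask] = (0.78, 0.70, 0.35)
    # awn-like speckle on the head
    speckle = rng.random((size, size)) < 0.25
    img[head_mask & speckle] = (0.62, 0.55, 0.25)

    sheath_mask = (
        ((xr / (0.16 * size)) ** 2 + ((yr - 0.30 * size) / (0.42 * size)) ** 2) <= 1.0
    ) & (yr >= sheath_top)
    img[sheath_mask] = (0.16, 0.30, 0.12)

    img = img * gain + rng.normal(0.0, noise_sd, size=img.shape)
    img = _box_blur(img, passes)
    return (np.clip(img, 0.0, 1.0) * 255).astype(np.uint8)


def head_pixel_count(image: np.ndarray) -> int:
    """Count golden head pixels (red channel dominating blue)."""
    img = image.astype(np.float64) / 255.0
    return int(np.sum((img[..., 0] > img[..., 2] + 0.15) & (img[..., 0] > 0.3)))


@dataclass
class SimDataset:
    config: SimConfig
    plants: list[SimPlant]
    weather: list[DailyWeather]
    climatology: MonthlyClimatology
    pool: list[IWC]


def _nuisance_seed(config_seed: int, plant_idx: int, day: int, img: int) -> int:
    return (config_seed * 1000003 + plant_idx * 10007 + day * 101 + img) % (2**31)


def build_dataset(
    config: SimConfig, seed: int | None = None, plant_seed: int | None = None
) -> SimDataset:
    """Simulate weather + phenology and render the full IWC pool in memory.

    ``plant_seed`` redraws the plants (thresholds, image nuisances)
    while keeping the weather identical — a matched-weather second
    field for anchor-transfer experiments.
    """
    base_seed = config.seed if seed is None else seed
    earliest = min(config.sowing_dates)
    start = earliest - dt.timedelta(days=config.history_days + 10)
    # enough days for sowing -> anthesis (~100 d) plus margins
    n_days = config.history_days + 10 + 200
    weather = simulate_weather(config, start, n_days, seed=base_seed)
    clim = make_climatology(config)
    plants = make_plants(config, seed=base_seed if plant_seed is None else plant_seed)
    assign_phenology(plants, weather, config)

    cum_by_group = {
        g: _cpdd_since(weather, d) for g, d in enumerate(config.sowing_dates)
    }
    window_cache: dict[dt.date, WeatherWindow] = {}
    pool: list[IWC] = []
    d_lo, d_hi = config.obs_days_to_anthesis
    s0 = config.emergence_start_frac
    for p_idx, plant in enumerate(plants):
        cum = cum_by_group[plant.sowing_group]
        for d in range(d_hi, d_lo - 1, -1):
            date = plant.anthesis_date - dt.timedelta(days=d)
            if date < plant.sowing_date or date not in cum:
                continue
            if date not in window_cache:
                window_cache[date] = build_weather_window(
                    weather, date, clim,
                    history_days=config.history_days,
                    forecast_days=config.forecast_days,
                )
            stage = cum[date] / plant.theta
            progress = float(np.clip((stage - s0) / (1.0 - s0), 0.0, 1.0))
            for img_i in range(config.images_per_day):
                pixels = render_head_image(
                    progress,
                    _nuisance_seed(
                        base_seed if plant_seed is None else plant_seed,
                        p_idx, d, img_i,
                    ),
                    size=config.image_size,
                    noise_sd=config.image_noise_sd,
                    blur_max_passes=config.blur_max_passes,
                )
                pool.append(
                    IWC(
                        plant_id=plant.plant_id,
                        capture_date=date,
                        days_to_anthesis=d,
                        image=HeadImage(pixels, source_id=f"{plant.plant_id}_d{d}_{img_i}",
                                        capture_date=date),
                        weather=window_cache[date],
                    )
                )
    return SimDataset(config, plants, weather, clim, pool)


def emit_dataset(config: SimConfig, out_dir, seed: int | None = None) -> Path:
    """Write images, manifest, weather, climatology and ground truth to disk."""
    from PIL import Image

    from .io import write_climatology_csv, write_manifest, write_weather_csv

    ds = build_dataset(config, seed=seed)
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for iwc in ds.pool:
        rel = f"images/{iwc.image.source_id}.png"
        Image.fromarray(iwc.image.pixels).save(out / rel)
        rows.append(
            {
                "plant_id": iwc.plant_id,
                "date": iwc.capture_date.isoformat(),
                "image_path": rel,
                "days_to_anthesis": iwc.days_to_anthesis,
            }
        )
    write_manifest(rows, out / "manifest.csv")
    write_weather_csv(ds.weather, out / "weather.csv")
    write_climatology_csv(ds.climatology, out / "climatology.csv")
    truth = {
        "seed": config.seed if seed is None else seed,
        "config": {k: str(v) for k, v in asdict(config).items()},
        "plants": [
            {
                "plant_id": p.plant_id,
                "sowing_group": p.sowing_group,
                "sowing_date": p.sowing_date.isoformat(),
                "theta": p.theta,
                "anthesis_date": p.anthesis_date.isoformat(),
            }
            for p in ds.plants
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out
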
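"""Photo-degree-day weather features and the per-observation weather window.

The phenology signal the model consumes is built from four daily
measurements (min/max temperature, sunlight duration, rainfall) plus two
derived indices:

* photo-degree days (PDD): half the diurnal temperature range times the
  sunlight duration, a combined heat-light accumulation index, and
* cumulative PDD (CPDD): the running sum of PDD, which tracks how much
  photothermal time a plant has accumulated.

Each observation of a plant carries a window of ``history_days`` days
before the imaging day, the imaging day itself, and ``forecast_days``
forecast days after it (default 90 + 1 + 6 = 97 rows).  Forecast days
have no measured sunlight; it is estimated from the forecast condition
category as a fixed fraction of the 20-year monthly mean sunlight.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: fraction of the monthly-mean sunlight assigned to each forecast category
CONDITION_FACTORS = {
    "sunny": 1.00,
    "mostly_sunny": 0.75,
    "mostly_cloudy": 0.50,
    "cloudy": 0.25,
    "shower": 0.00,
}

WINDOW_COLUMNS = ("tmin", "tmax", "sunlight", "rainfall", "pdd", "cpdd")


@dataclass(frozen=True)
class DailyWeather:
    """One day of weather.  ``sunlight`` may be None on forecast days."""

    date: dt.date
    tmin: float
    tmax: float
    sunlight: float | None
    rainfall: float
    condition: str = "none"
    is_forecast: bool = False

    def __post_init__(self):
        if self.tmax < self.tmin:
            raise ValidationError(
                f"tmax ({self.tmax}) < tmin ({self.tmin}) on {self.date}"
            )
        if self.sunlight is not None and not (0.0 <= self.sunlight <= 24.0):
            raise ValidationError(f"sunlight out of [0, 24] on {self.date}")
        if self.rainfall < 0:
            raise ValidationError(f"negative rainfall on {self.date}")
        if self.condition not in CONDITION_FACTORS and self.condition != "none":
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.sunlight is None and self.condition == "none":
            raise ValidationError(
                f"day {self.date} has neither measured sunlight nor a condition"
            )


@dataclass(frozen=True)
class MonthlyClimatology:
    """Month (1-12) -> long-term mean daily sunlight hours."""

    mean_sunlight: dict[int, float]

    def __post_init__(self):
        missing = set(range(1, 13)) - set(self.mean_sunlight)
        if missing:
            raise ValidationError(f"climatology missing months {sorted(missing)}")
        for month, hours in self.mean_sunlight.items():
            if not (0.0 < hours < 24.0):
                raise ValidationError(
                    f"climatology mean for month {month} out of (0, 24): {hours}"
                )

    def __getitem__(self, month: int) -> float:
        if month not in self.mean_sunlight:
            raise ValidationError(f"month {month} absent from climatology")
        return self.mean_sunlight[month]


@dataclass
class WeatherWindow:
    """T x 6 matrix of daily (tmin, tmax, sunlight, rainfall, PDD, CPDD)."""

    matrix: np.ndarray
    imaging_row_index: int
    start_date: dt.date

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(WINDOW_COLUMNS):
            raise ValidationError(
                f"window matrix must be T x {len(WINDOW_COLUMNS)}, got {self.matrix.shape}"
            )
        if not (0 <= self.imaging_row_index < self.matrix.shape[0]):
            raise ValidationError("imaging_row_index outside window")

    @property
    def n_days(self) -> int:
        return self.matrix.shape[0]

    @property
    def imaging_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=int(self.imaging_row_index))


def compute_pdd(tmax: float, tmin: float, sunlight: float) -> float:
    """Daily photo-degree days: ((tmax - tmin) / 2) * sunlight."""
    if tmax < tmin:
        raise ValidationError(f"tmax ({tmax}) < tmin ({tmin})")
    if sunlight < 0:
        raise ValidationError(f"negative sunlight ({sunlight})")
    return ((tmax - tmin) / 2.0) * sunlight


def compute_cpdd(pdd_series) -> np.ndarray:
    """Cumulative photo-degree days: element k is the sum of PDD[0..k]."""
    pdd = np.asarray(pdd_series, dtype=np.float64)
    if pdd.size == 0:
        raise ValidationError("empty PDD series")
    return np.cumsum(pdd)


def estimate_forecast_sunlight(
    condition: str, month: int, clim: MonthlyClimatology
) -> float:
    """Sunlight estimate for a forecast day: category factor x monthly mean."""
    if condition not in CONDITION_FACTORS:
        raise ValidationError(
            f"unknown forecast condition {condition!r}; "
            f"expected one of {sorted(CONDITION_FACTORS)}"
        )
    return CONDITION_FACTORS[condition] * clim[month]


def build_weather_window(
    records: list[DailyWeather],
    imaging_date: dt.date,
    clim: MonthlyClimatology,
    history_days: int = 90,
    forecast_days: int = 6,
) -> WeatherWindow:
    """Assemble the T x 6 window around one imaging date.

    Rows are consecutive calendar days, oldest first.  Rows strictly
    after the imaging date are treated as forecasts: their sunlight is
    estimated from the recorded condition category regardless of any
    measured value, mirroring deployment where future sunlight is never
    observed.  CPDD is accumulated within the window (row 0 contributes
    its own PDD).
    """
    if history_days < 0 or forecast_days < 0:
        raise ValidationError("history_days and forecast_days must be >= 0")
    by_date: dict[dt.date, DailyWeather] = {}
    for rec in records:
        if rec.date in by_date:
            raise ValidationError(f"duplicate weather record for {rec.date}")
        by_date[rec.date] = rec

    start = imaging_date - dt.timedelta(days=history_days)
    dates = [start + dt.timedelta(days=k) for k in range(history_days + 1 + forecast_days)]
    missing = [d for d in dates if d not in by_date]
    if missing:
        raise ValidationError(
            f"weather records missing for {len(missing)} day(s): "
            f"{missing[0]} .. {missing[-1]}"
        )

    rows = np.empty((len(dates), 6), dtype=np.float64)
    for i, d in enumerate(dates):
        rec = by_date[d]
        if d > imaging_date:
            sunlight = estimate_forecast_sunlight(rec.condition, d.month, clim)
        else:
            if rec.sunlight is None:
                raise ValidationError(f"historical day {d} lacks measured sunlight")
            sunlight = rec.sunlight
        pdd = compute_pdd(rec.tmax, rec.tmin, sunlight)
        rows[i] = (rec.tmin, rec.tmax, sunlight, rec.rainfall, pdd, 0.0)
    rows[:, 5] = compute_cpdd(rows[:, 4])
    return WeatherWindow(rows, imaging_row_index=history_days, start_date=start)


@dataclass(frozen=True)
class WindowStats:
    """Per-column mean/sd for z-scoring windows; fit on the training split."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, windows: list[np.ndarray]) -> "WindowStats":
        stacked = np.concatenate([np.asarray(w).reshape(-1, len(WINDOW_COLUMNS)) for w in windows])
        return cls(mean=stacked.mean(axis=0), sd=stacked.std(axis=0))


def normalize_window(window, stats: WindowStats) -> np.ndarray:
    """Per-column z-score; constant columns (sd = 0) map to zero."""
    mat = window.matrix if isinstance(window, WeatherWindow) else np.asarray(window)
    if mat.shape[1] != stats.mean.shape[0]:
        raise ValidationError(
            f"window has {mat.shape[1]} columns but stats cover {stats.mean.shape[0]}"
        )
    sd = np.where(stats.sd == 0, 1.0, stats.sd)
    out = (mat - stats.mean) / sd
    out[:, stats.sd == 0] = 0.0
    return out


def denormalize_window(matrix: np.ndarray, stats: WindowStats) -> np.ndarray:
    """Inverse of :func:`normalize_window` where all sd > 0."""
    if np.any(stats.sd == 0):
        raise ValidationError("cannot invert normalisation of a constant column")
    return np.asarray(matrix) * stats.sd + stats.mean
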
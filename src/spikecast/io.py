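"""Readers and writers for the package's plain-text interchange formats.

Manifest CSV: ``plant_id,date,image_path,days_to_anthesis`` (ISO dates,
day count may be blank in inference mode).  Weather CSV:
``date,tmin_c,tmax_c,sunlight_h,rain_mm,condition,is_forecast``.
Climatology CSV: ``month,mean_sunlight_h``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .weather import CONDITION_FACTORS, DailyWeather, MonthlyClimatology

MANIFEST_COLUMNS = ["plant_id", "date", "image_path", "days_to_anthesis"]
WEATHER_COLUMNS = [
    "date", "tmin_c", "tmax_c", "sunlight_h", "rain_mm", "condition", "is_forecast",
]


@dataclass
class ManifestRecord:
    plant_id: str
    date: dt.date
    image_path: str
    days_to_anthesis: int | None


def _parse_date(value: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"row {row}: unparsable date {value!r}") from exc


def read_manifest(path) -> list[ManifestRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest missing columns {sorted(missing)}")
    records = []
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        raw_days = str(rec.days_to_anthesis).strip()
        days = None
        if raw_days:
            try:
                days = int(raw_days)
            except ValueError as exc:
                raise ValidationError(
                    f"row {row}: days_to_anthesis {raw_days!r} is not an integer"
                ) from exc
            if days < 0:
                raise ValidationError(f"row {row}: negative days_to_anthesis")
        records.append(
            ManifestRecord(
                plant_id=str(rec.plant_id),
                date=_parse_date(rec.date, row),
                image_path=str(rec.image_path),
                days_to_anthesis=days,
            )
        )
    return records


def write_manifest(rows: list[dict], path) -> None:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def read_weather_csv(path) -> list[DailyWeather]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"weather CSV missing columns {sorted(missing)}")
    records = []
    seen: dict[dt.date, int] = {}
    for row, rec in enumerate(df.itertuples(index=False), start=2):
        date = _parse_date(rec.date, row)
        if date in seen:
            raise ValidationError(
                f"row {row}: duplicate date {date} (first at row {seen[date]})"
            )
        seen[date] = row
        sunlight = str(rec.sunlight_h).strip()
        condition = str(rec.condition).strip() or "none"
        is_forecast = str(rec.is_forecast).strip().lower() in ("1", "true", "yes")
        if is_forecast and condition not in CONDITION_FACTORS:
            raise ValidationError(
                f"row {row}: forecast day has invalid condition {condition!r}"
            )
        try:
            records.append(
                DailyWeather(
                    date=date,
                    tmin=float(rec.tmin_c),
                    tmax=float(rec.tmax_c),
                    sunlight=float(sunlight) if sunlight else None,
                    rainfall=float(rec.rain_mm),
                    condition=condition,
                    is_forecast=is_forecast,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {row}: {exc}") from exc
    records.sort(key=lambda r: r.date)
    return records


def write_weather_csv(records: list[DailyWeather], path) -> None:
    df = pd.DataFrame(
        {
            "date": [r.date.isoformat() for r in records],
            "tmin_c": [r.tmin for r in records],
            "tmax_c": [r.tmax for r in records],
            "sunlight_h": ["" if r.sunlight is None else r.sunlight for r in records],
            "rain_mm": [r.rainfall for r in records],
            "condition": [r.condition for r in records],
            "is_forecast": [int(r.is_forecast) for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_climatology_csv(path) -> MonthlyClimatology:
    df = pd.read_csv(path)
    if not {"month", "mean_sunlight_h"} <= set(df.columns):
        raise ValidationError("climatology CSV needs columns month,mean_sunlight_h")
    return MonthlyClimatology(
        {int(m): float(h) for m, h in zip(df["month"], df["mean_sunlight_h"])}
    )


def write_climatology_csv(clim: MonthlyClimatology, path) -> None:
    df = pd.DataFrame(
        {
            "month": sorted(clim.mean_sunlight),
            "mean_sunlight_h": [clim.mean_sunlight[m] for m in sorted(clim.mean_sunlight)],
        }
    )
    df.to_csv(path, index=False)


def load_pool(
    data_dir,
    history_days: int = 90,
    forecast_days: int = 6,
) -> list:
    """Load a dataset directory (manifest + weather + climatology) into IWCs."""
    from PIL import Image

    from .dataset import IWC
    from .imageprep import HeadImage
    from .weather import build_weather_window

    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / "manifest.csv")
    weather = read_weather_csv(data_dir / "weather.csv")
    clim = read_climatology_csv(data_dir / "climatology.csv")
    windows = {}
    pool = []
    for rec in manifest:
        if rec.date not in windows:
            windows[rec.date] = build_weather_window(
                weather, rec.date, clim, history_days, forecast_days
            )
        pixels = np.asarray(Image.open(data_dir / rec.image_path))
        pool.append(
            IWC(
                plant_id=rec.plant_id,
                capture_date=rec.date,
                days_to_anthesis=rec.days_to_anthesis,
                image=HeadImage(pixels, source_id=rec.image_path, capture_date=rec.date),
                weather=windows[rec.date],
            )
        )
    return pool
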
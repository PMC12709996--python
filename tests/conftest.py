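"""Shared fixtures.

The expensive pieces — the default synthetic world and the comparator
trained on it — are session-scoped so the end-to-end tests share one
training run.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from spikecast.dataset import IWC, PairSamplerConfig, split_epoch_sets

hypothesis_settings.register_profile("deterministic", derandomize=True,
                                     deadline=None)
hypothesis_settings.load_profile("deterministic")
from spikecast.imageprep import HeadImage
from spikecast.networks import SiameseComparator
from spikecast.simulate import SimConfig, build_dataset
from spikecast.training import TrainConfig, train_meta
from spikecast.weather import WeatherWindow

# problem sizes for the desk-scale benchmark (see docs/methods.md)
BENCH_N_TRAIN = 2000
BENCH_N_VAL = 400
BENCH_EPOCHS = 10
BENCH_TRAIN = TrainConfig(
    epochs_max=BENCH_EPOCHS, batch_size=128, lr_max=1e-3, lr_min=1e-5,
    patience=BENCH_EPOCHS, seed=5,
)


def metadata_iwc(plant_id: str, days: int, date: dt.date | None = None) -> IWC:
    """IWC with labels only (no image/weather) for sampler-level tests."""
    return IWC(
        plant_id=plant_id,
        capture_date=date or dt.date(2023, 8, 1),
        days_to_anthesis=days,
    )


def feature_iwc(
    plant_id: str, days: int, t_rows: int = 12, image_size: int = 8,
    rng: np.random.Generator | None = None,
) -> IWC:
    """IWC whose weather window trivially encodes its day count.

    Every window column equals ``days``; the image is uninformative
    noise.  Used for separable-fixture training tests.
    """
    rng = rng or np.random.default_rng(days)
    date = dt.date(2023, 8, 1)
    mat = np.full((t_rows, 6), float(days))
    window = WeatherWindow(mat, imaging_row_index=t_rows - 1,
                           start_date=date - dt.timedelta(days=t_rows - 1))
    pixels = rng.integers(0, 255, size=(image_size, image_size, 3)).astype(np.uint8)
    return IWC(
        plant_id=plant_id,
        capture_date=date,
        days_to_anthesis=days,
        image=HeadImage(pixels, source_id=plant_id),
        weather=window,
    )


@pytest.fixture(scope="session")
def bench_world():
    """The default synthetic study conditions: 120 plants, 2 sowing groups."""
    return build_dataset(SimConfig())


@pytest.fixture(scope="session")
def bench_model(bench_world):
    """Comparator trained once on the benchmark world's pair sets."""
    pairs = split_epoch_sets(
        bench_world.pool,
        PairSamplerConfig(n_train=BENCH_N_TRAIN, n_val=BENCH_N_VAL, seed=11),
    )
    model = SiameseComparator(seed=5)
    _, report = train_meta(model, pairs[0], pairs[1], BENCH_TRAIN)
    return model, report
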
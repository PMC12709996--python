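"""Image-Weather Combos (IWCs), pair labelling, and the pair sampler.

An IWC is one observation of one plant: a head-image crop plus the
surrounding weather window.  Training never needs per-pair annotation:
from n IWCs with known days-to-anthesis, ordered pairs are drawn and
labelled by comparing the two day counts, which is what lets a modest
pool support tens of thousands of distinct training comparisons.

The sampler enforces two composition quotas, each in expectation by an
independent Bernoulli draw per pair (an exact-count mode is available):

* 80 % of pairs juxtapose distinct days-to-anthesis values, 20 % share
  the same value;
* 95 % of pairs use two different plants, 5 % the same plant.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .imageprep import HeadImage
from .weather import WeatherWindow


@dataclass
class IWC:
    """One plant observation.  ``image`` may be deferred (lazy pools)."""

    plant_id: str
    capture_date: dt.date
    days_to_anthesis: int | None = None
    image: HeadImage | None = None
    weather: WeatherWindow | None = None

    def __post_init__(self):
        if self.days_to_anthesis is not None and self.days_to_anthesis < 0:
            raise ValidationError(
                f"negative days_to_anthesis for {self.plant_id} on {self.capture_date}"
            )
        if self.weather is not None and self.weather.imaging_date != self.capture_date:
            raise ValidationError(
                f"weather window imaging day {self.weather.imaging_date} "
                f"!= capture date {self.capture_date}"
            )


BINARY = "binary"
TERNARY = "ternary"
_BINARY_VALUES = ("negative", "positive")
_TERNARY_VALUES = ("negative", "neutral", "positive")


@dataclass(frozen=True)
class PairLabel:
    scheme: str
    value: str

    def __post_init__(self):
        allowed = _BINARY_VALUES if self.scheme == BINARY else _TERNARY_VALUES
        if self.scheme not in (BINARY, TERNARY):
            raise ValidationError(f"unknown labelling scheme {self.scheme!r}")
        if self.value not in allowed:
            raise ValidationError(
                f"label {self.value!r} not permitted by scheme {self.scheme!r}"
            )

    @property
    def class_index(self) -> int:
        allowed = _BINARY_VALUES if self.scheme == BINARY else _TERNARY_VALUES
        return allowed.index(self.value)


@dataclass
class IWCPair:
    first: IWC
    second: IWC
    label: PairLabel


def _check_days(d1: int, d2: int) -> None:
    if d1 < 0 or d2 < 0:
        raise ValidationError(f"days to anthesis must be >= 0, got ({d1}, {d2})")


def binary_pair_label(d1: int, d2: int) -> PairLabel:
    """Negative iff the first IWC's days-to-anthesis >= the second's.

    Ties are deliberately negative: "equal or longer" is one class, so
    the rule is asymmetric under operand swap at d1 == d2.
    """
    _check_days(d1, d2)
    return PairLabel(BINARY, "negative" if d1 >= d2 else "positive")


def ternary_pair_label(d1: int, d2: int) -> PairLabel:
    """Three classes on the day difference d1 - d2.

    positive: first flowers at least two days sooner (diff <= -2);
    neutral: within one day (|diff| <= 1); negative: diff >= +2.  The
    class boundaries are symmetric at |diff| = 2.
    """
    _check_days(d1, d2)
    diff = d1 - d2
    if diff <= -2:
        return PairLabel(TERNARY, "positive")
    if diff >= 2:
        return PairLabel(TERNARY, "negative")
    return PairLabel(TERNARY, "neutral")


def label_for(scheme: str, d1: int, d2: int) -> PairLabel:
    if scheme == BINARY:
        return binary_pair_label(d1, d2)
    if scheme == TERNARY:
        return ternary_pair_label(d1, d2)
    raise ValidationError(f"unknown labelling scheme {scheme!r}")


@dataclass
class PairSamplerConfig:
    n_train: int = 24000
    n_val: int = 6000
    distinct_day_frac: float = 0.80
    distinct_id_frac: float = 0.95
    seed: int = 0
    exact_counts: bool = False

    def __post_init__(self):
        if not (0.0 <= self.distinct_day_frac <= 1.0):
            raise ValidationError("distinct_day_frac must be in [0, 1]")
        if not (0.0 <= self.distinct_id_frac <= 1.0):
            raise ValidationError("distinct_id_frac must be in [0, 1]")
        if self.n_train <= 0 or self.n_val <= 0:
            raise ValidationError("pair counts must be positive")


class _PoolIndex:
    def __init__(self, pool: list[IWC]):
        if not pool:
            raise ValidationError("empty IWC pool")
        for iwc in pool:
            if iwc.days_to_anthesis is None:
                raise ValidationError(
                    f"IWC {iwc.plant_id}@{iwc.capture_date} lacks days_to_anthesis"
                )
        self.days = np.array([iwc.days_to_anthesis for iwc in pool])
        plants = [iwc.plant_id for iwc in pool]
        code = {p: c for c, p in enumerate(sorted(set(plants)))}
        self.plant_codes = np.array([code[p] for p in plants])
        if len(set(plants)) < 2:
            raise ValidationError(
                "distinct-id bucket unsatisfiable: pool has a single plant id"
            )
        if len(set(self.days.tolist())) < 2:
            raise ValidationError(
                "distinct-day bucket unsatisfiable: pool has a single day value"
            )
        self.by_day: dict[int, np.ndarray] = {}
        self.by_plant: dict[int, np.ndarray] = {}
        self.by_plant_day: dict[tuple[int, int], np.ndarray] = {}
        idx = np.arange(len(pool))
        for d in np.unique(self.days):
            self.by_day[int(d)] = idx[self.days == d]
        for p in np.unique(self.plant_codes):
            self.by_plant[int(p)] = idx[self.plant_codes == p]
        for i in idx:
            key = (int(self.plant_codes[i]), int(self.days[i]))
            self.by_plant_day.setdefault(key, []).append(i)
        self.by_plant_day = {k: np.array(v) for k, v in self.by_plant_day.items()}


def _draw_partner(
    index: _PoolIndex,
    first: int,
    same_day: bool,
    same_id: bool,
    rng: np.random.Generator,
) -> int:
    day = int(index.days[first])
    plant = int(index.plant_codes[first])
    if same_day and same_id:
        candidates = index.by_plant_day[(plant, day)]
        ok = candidates != first
    elif same_day:
        candidates = index.by_day[day]
        ok = index.plant_codes[candidates] != plant
    elif same_id:
        candidates = index.by_plant[plant]
        ok = index.days[candidates] != day
    else:
        candidates = np.arange(len(index.days))
        ok = (index.plant_codes != plant) & (index.days != day)
    # rejection sampling on the candidate list, then exhaustive fallback
    for _ in range(32):
        j = int(candidates[rng.integers(len(candidates))])
        if same_day and same_id:
            if j != first:
                return j
        elif same_day:
            if index.plant_codes[j] != plant:
                return j
        elif same_id:
            if index.days[j] != day:
                return j
        else:
            if index.plant_codes[j] != plant and index.days[j] != day:
                return j
    valid = candidates[ok]
    if len(valid) == 0:
        # degenerate corner (e.g. a single image for this plant-day):
        # fall back to pairing the IWC with itself, deterministically
        return first
    return int(valid[rng.integers(len(valid))])


def sample_pairs(
    pool: list[IWC],
    config: PairSamplerConfig,
    scheme: str = BINARY,
    n: int | None = None,
    seed: int | None = None,
) -> list[IWCPair]:
    """Draw ``n`` labelled pairs under the composition quotas.

    Each pair independently decides (same-day vs distinct-day) and
    (same-plant vs distinct-plant), then samples the two members
    uniformly among IWCs meeting the joint constraint.  The draw is a
    pure function of (pool order, seed).
    """
    index = _PoolIndex(pool)
    n = config.n_train if n is None else n
    seed = config.seed if seed is None else seed
    rng = np.random.Generator(np.random.PCG64(seed))
    if config.exact_counts:
        n_same_day = int(round(n * (1.0 - config.distinct_day_frac)))
        n_same_id = int(round(n * (1.0 - config.distinct_id_frac)))
        same_day_flags = np.zeros(n, dtype=bool)
        same_day_flags[:n_same_day] = True
        rng.shuffle(same_day_flags)
        same_id_flags = np.zeros(n, dtype=bool)
        same_id_flags[:n_same_id] = True
        rng.shuffle(same_id_flags)
    else:
        same_day_flags = rng.random(n) >= config.distinct_day_frac
        same_id_flags = rng.random(n) >= config.distinct_id_frac
    pairs: list[IWCPair] = []
    n_pool = len(pool)
    for k in range(n):
        first = int(rng.integers(n_pool))
        second = _draw_partner(
            index, first, bool(same_day_flags[k]), bool(same_id_flags[k]), rng
        )
        label = label_for(
            scheme, pool[first].days_to_anthesis, pool[second].days_to_anthesis
        )
        pairs.append(IWCPair(pool[first], pool[second], label))
    return pairs


def split_epoch_sets(
    pool: list[IWC], config: PairSamplerConfig, scheme: str = BINARY
) -> tuple[list[IWCPair], list[IWCPair]]:
    """Fixed train/validation pair sets with disjoint random streams.

    The same sets are reused every epoch (fixed-seed protocol); pass a
    fresh config seed to resample.
    """
    train = sample_pairs(pool, config, scheme, n=config.n_train, seed=config.seed)
    val = sample_pairs(pool, config, scheme, n=config.n_val, seed=config.seed + 1)
    return train, val
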
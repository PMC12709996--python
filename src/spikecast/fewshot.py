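"""Anchor construction and the ten-cycle one-/five-shot evaluation protocol.

At deployment time the trained comparator is never retrained.  Instead,
for a critical day n, a small support set of plants known to be exactly
n days from anthesis is imaged; the mean of their 256-d features is the
*anchor* for that day.  A query plant is classified by feeding (query
feature, anchor) to the comparative head: the positive class means the
query flowers within n days, negative that it needs more than n days.

The evaluation protocol repeats this ``cycles`` times (default ten) per
critical day, re-drawing supports and queries each cycle while keeping
the selected support plants identical across the critical days within a
cycle, and reports the per-day mean F1.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import IWC
from .errors import ValidationError
from .networks import SiameseComparator
from .weather import normalize_window

CRITICAL_DAYS = (8, 10, 12, 14, 16)


def f1_score(tp: int, fp: int, fn: int) -> float:
    """F1 = 2 TP / (2 TP + FP + FN); defined as 0 for an empty table."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("confusion counts must be >= 0")
    denom = 2 * tp + fp + fn
    if denom == 0:
        warnings.warn("F1 undefined for all-zero confusion counts; returning 0")
        return 0.0
    return 2.0 * tp / denom


@dataclass
class Anchor:
    """Mean feature vector of a support set for one critical day."""

    vector: np.ndarray
    critical_day: int
    support_size: int

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if not np.all(np.isfinite(self.vector)):
            raise ValidationError("anchor vector has non-finite components")
        if self.support_size < 1:
            raise ValidationError("anchor support size must be >= 1")


def _as_extractor(model):
    """Accept a SiameseComparator, an (extractor, head) tuple, or a
    callable list[IWC] -> (N, d) array."""
    if isinstance(model, tuple):
        return _as_extractor(model[0])
    if isinstance(model, SiameseComparator):
        if model.window_stats is None:
            raise ValidationError(
                "model has no window statistics; train it (or load a "
                "checkpoint) before inference"
            )

        def extract(iwcs: list[IWC]) -> np.ndarray:
            images = np.stack([iwc.image.pixels for iwc in iwcs])
            # windows are shared across plants imaged the same day: run
            # the recurrent branch once per distinct window object
            win_ids: dict[int, int] = {}
            unique = []
            idx = np.empty(len(iwcs), dtype=np.int64)
            for i, iwc in enumerate(iwcs):
                key = id(iwc.weather)
                if key not in win_ids:
                    win_ids[key] = len(unique)
                    unique.append(
                        normalize_window(iwc.weather, model.window_stats)
                    )
                idx[i] = win_ids[key]
            windows = np.stack(unique).astype(np.float32)
            return model.extract_pool(images, windows, idx)

        return extract
    if callable(model):
        return model
    raise ValidationError("extractor must be a model or a callable")


def _as_head(model):
    if isinstance(model, tuple):
        return _as_head(model[1])
    if isinstance(model, SiameseComparator):
        return model.compare_features
    if callable(model):
        return model
    raise ValidationError("comparative head must be a model or a callable")


def build_anchor(support: list[IWC], extractor, n: int) -> Anchor:
    """Element-wise mean of the support features; permutation-invariant."""
    if not support:
        raise ValidationError("empty support set")
    days = {iwc.days_to_anthesis for iwc in support}
    if days != {n}:
        raise ValidationError(
            f"support set for critical day {n} contains days {sorted(days)}"
        )
    feats = _as_extractor(extractor)(support)
    return Anchor(np.mean(feats, axis=0), critical_day=n, support_size=len(support))


def predict_within_n(query, anchor: Anchor, extractor, head) -> str:
    """Classify one query IWC (or feature vector) against an anchor.

    Binary: ``"within"`` (will flower within n days) or ``"beyond"``.
    Ternary: ``"before"`` / ``"within_one_day"`` / ``"after"`` the
    critical date.  Note the comparator's tie rule (equal day counts are
    negative), so a query exactly at the boundary lands on the "beyond"
    side.
    """
    if isinstance(query, IWC):
        feat = _as_extractor(extractor)([query])[0]
    else:
        feat = np.asarray(query)
    scores = np.atleast_2d(_as_head(head)(feat[None, :], anchor.vector[None, :]))
    cls = int(np.argmax(scores[0]))
    n_classes = scores.shape[1]
    if n_classes == 2:
        return "within" if cls == 1 else "beyond"
    return ("after", "within_one_day", "before")[cls]


@dataclass
class CycleReport:
    """Per-critical-day F1 across evaluation cycles."""

    critical_days: tuple[int, ...]
    shots: int
    cycles: int
    f1: dict[int, list[float]] = field(default_factory=dict)
    confusion: dict[int, list[dict]] = field(default_factory=dict)

    @property
    def mean_f1(self) -> dict[int, float]:
        return {n: float(np.mean(v)) for n, v in self.f1.items()}

    @property
    def overall_mean_f1(self) -> float:
        return float(np.mean([np.mean(v) for v in self.f1.values()]))

    def to_dict(self) -> dict:
        return {
            "critical_days": list(self.critical_days),
            "shots": self.shots,
            "cycles": self.cycles,
            "f1": {str(n): v for n, v in self.f1.items()},
            "mean_f1": {str(n): v for n, v in self.mean_f1.items()},
            "overall_mean_f1": self.overall_mean_f1,
            "confusion": {str(n): v for n, v in self.confusion.items()},
        }


def _group_pool(pool: list[IWC]):
    """plant -> day -> list of pool indices."""
    groups: dict[str, dict[int, list[int]]] = {}
    for i, iwc in enumerate(pool):
        if iwc.days_to_anthesis is None:
            raise ValidationError("evaluation pool requires days_to_anthesis")
        groups.setdefault(iwc.plant_id, {}).setdefault(
            int(iwc.days_to_anthesis), []
        ).append(i)
    return groups


def pool_features(model, pool: list[IWC], cache: dict | None = None) -> np.ndarray:
    """Extract (and optionally memoise) features for a whole pool."""
    if cache is not None and id(pool) in cache:
        return cache[id(pool)]
    feats = _as_extractor(model)(pool)
    if cache is not None:
        cache[id(pool)] = feats
    return feats


def _score_within(head, feats: np.ndarray, anchor_vec: np.ndarray,
                  chunk: int = 8192) -> np.ndarray:
    """Vote 'within n days' for every feature row against one anchor."""
    votes = np.empty(len(feats), dtype=bool)
    for lo in range(0, len(feats), chunk):
        sl = slice(lo, lo + chunk)
        scores = np.atleast_2d(
            head(feats[sl], np.broadcast_to(anchor_vec, (len(feats[sl]), anchor_vec.size)))
        )
        votes[sl] = np.argmax(scores, axis=1) == 1
    return votes


def run_protocol(
    model,
    pool: list[IWC],
    critical_days: tuple[int, ...] = CRITICAL_DAYS,
    shots: int = 5,
    cycles: int = 10,
    seed: int = 0,
    anchor_pool: list[IWC] | None = None,
    images_per_support_plant: int = 8,
    boundary: str = "inclusive",
    aggregate: str = "majority",
    feature_cache: dict | None = None,
) -> CycleReport:
    """Ten-cycle one-/five-shot evaluation with per-day F1.

    Supports are drawn from ``anchor_pool`` (defaults to ``pool``); when
    the two pools coincide, support plants are excluded from the query
    set of the same cycle.  Within a cycle the same support plants are
    reused across all critical days.  Cycle c uses seed + c, so each
    cycle is independently reproducible.  Queries are scored per image
    and aggregated to one decision per (plant, observation day) by
    majority vote (``aggregate='per_image'`` keeps image-level
    decisions); ground truth is days_to_anthesis <= n (``boundary=
    'strict'`` uses < n).
    """
    if shots < 1:
        raise ValidationError("shots must be >= 1")
    if boundary not in ("inclusive", "strict"):
        raise ValidationError("boundary must be 'inclusive' or 'strict'")
    if aggregate not in ("majority", "per_image"):
        raise ValidationError("aggregate must be 'majority' or 'per_image'")
    transfer = anchor_pool is not None
    a_pool = anchor_pool if transfer else pool
    head = _as_head(model)

    groups_q = _group_pool(pool)
    groups_a = _group_pool(a_pool)
    # plants usable for supports must be observed at every critical day
    eligible = sorted(
        p for p, days in groups_a.items() if all(n in days for n in critical_days)
    )
    if len(eligible) < shots:
        raise ValidationError(
            f"only {len(eligible)} plants observed at all critical days "
            f"{critical_days}; need {shots} for the support bucket"
        )

    feats_q = pool_features(model, pool, feature_cache)
    feats_a = feats_q if not transfer else pool_features(model, a_pool, feature_cache)

    # flatten query groups for vectorised aggregation
    q_plants_all = sorted(groups_q)
    g_plant, g_day, g_slices, flat = [], [], [], []
    for p in q_plants_all:
        for day in sorted(groups_q[p]):
            idxs = groups_q[p][day]
            g_plant.append(p)
            g_day.append(day)
            g_slices.append((len(flat), len(flat) + len(idxs)))
            flat.extend(idxs)
    flat = np.asarray(flat)
    g_day = np.asarray(g_day)
    g_lo = np.asarray([s[0] for s in g_slices])
    g_hi = np.asarray([s[1] for s in g_slices])
    g_size = g_hi - g_lo
    g_plant = np.asarray(g_plant)

    report = CycleReport(tuple(critical_days), shots, cycles,
                         {n: [] for n in critical_days},
                         {n: [] for n in critical_days})
    for c in range(cycles):
        rng = np.random.Generator(np.random.PCG64(seed + c))
        support_plants = set(rng.choice(eligible, size=shots, replace=False))
        if transfer:
            query_mask = np.ones(len(g_plant), dtype=bool)
        else:
            query_mask = ~np.isin(g_plant, list(support_plants))
        if not query_mask.any():
            raise ValidationError("no query plants left after support selection")
        for n in critical_days:
            support_idx: list[int] = []
            for p in sorted(support_plants):
                idxs = groups_a[p][n]
                take = min(images_per_support_plant, len(idxs))
                support_idx.extend(
                    rng.choice(idxs, size=take, replace=False).tolist()
                )
            anchor = Anchor(
                feats_a[support_idx].mean(axis=0), n, len(support_idx)
            )
            votes = _score_within(head, feats_q, anchor.vector)
            within_counts = np.add.reduceat(votes[flat].astype(np.int64), g_lo)
            truth = g_day <= n if boundary == "inclusive" else g_day < n
            if aggregate == "majority":
                predicted = within_counts > g_size / 2.0
                pred_pos = predicted[query_mask].astype(np.int64)
                true_pos = truth[query_mask]
                weights = np.ones(query_mask.sum(), dtype=np.int64)
            else:
                pred_pos = within_counts[query_mask]
                true_pos = truth[query_mask]
                weights = g_size[query_mask]
            tp = int(np.sum(np.where(true_pos, pred_pos, 0)))
            fn = int(np.sum(np.where(true_pos, weights - pred_pos, 0)))
            fp = int(np.sum(np.where(~true_pos, pred_pos, 0)))
            tn = int(np.sum(np.where(~true_pos, weights - pred_pos, 0)))
            report.f1[n].append(f1_score(tp, fp, fn))
            report.confusion[n].append({"tp": tp, "fp": fp, "fn": fn, "tn": tn})
    return report
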
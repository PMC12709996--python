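"""Meta-learning trainer for the pairwise comparator.

The trainer iterates over fixed epoch pair sets and applies four
stabilisation techniques: cosine-annealed learning rate, exponential
moving average (EMA) of parameters, label smoothing, and an Adam
optimiser with optional decoupled weight decay / AMSGrad.  Validation F1
is computed on the EMA parameters after every epoch and drives early
stopping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .dataset import BINARY, IWCPair, TERNARY
from .errors import ValidationError
from .networks import SiameseComparator, preprocess_images
from .nn import Tensor
from .weather import WindowStats, normalize_window


def cosine_lr(t: int, total: int, lr_max: float, lr_min: float) -> float:
    """Cosine annealing: lr_min + 0.5 (lr_max - lr_min)(1 + cos(pi t / T))."""
    if total < 1:
        raise ValidationError("total steps must be >= 1")
    if not (0 <= t <= total):
        raise ValidationError(f"step {t} outside [0, {total}]")
    return lr_min + 0.5 * (lr_max - lr_min) * (1.0 + math.cos(math.pi * t / total))


def smoothed_cross_entropy(
    scores: Tensor, true_class: np.ndarray, eps: float, n_classes: int
) -> Tensor:
    """Cross-entropy against a label-smoothed target distribution.

    The target assigns 1 - eps to the true class and eps / (n_classes - 1)
    to each other class; eps = 0 recovers standard cross-entropy.
    """
    if not (0.0 <= eps < 1.0):
        raise ValidationError("label smoothing eps must be in [0, 1)")
    true_class = np.asarray(true_class)
    if np.any(true_class < 0) or np.any(true_class >= n_classes):
        raise ValidationError("class index out of range")
    target = np.full(
        (true_class.size, n_classes),
        eps / (n_classes - 1) if n_classes > 1 else 0.0,
        dtype=np.float32,
    )
    target[np.arange(true_class.size), true_class] = 1.0 - eps
    logp = nn.log_softmax(scores, axis=-1)
    return -(Tensor(target) * logp).sum(axis=-1).mean()


# re-exported here because EMA is one of the trainer's four techniques
from .nn import ema_update  # noqa: E402


@dataclass
class TrainConfig:
    epochs_max: int = 50
    batch_size: int = 32
    lr_max: float = 1e-4
    lr_min: float = 1e-6
    label_smooth_eps: float = 0.1
    ema_decay: float = 0.999
    patience: int = 5
    seed: int = 0
    scheme: str = BINARY
    weight_decay: float = 0.0
    amsgrad: bool = False

    def __post_init__(self):
        if not (0.0 <= self.label_smooth_eps < 1.0):
            raise ValidationError("label_smooth_eps must be in [0, 1)")
        if not (0.0 <= self.ema_decay <= 1.0):
            raise ValidationError("ema_decay must be in [0, 1]")
        if self.patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.lr_min > self.lr_max:
            raise ValidationError("lr_min must be <= lr_max")
        if self.scheme not in (BINARY, TERNARY):
            raise ValidationError(f"unknown scheme {self.scheme!r}")


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_f1: list[float] = field(default_factory=list)  # on EMA parameters
    val_f1_raw: list[float] = field(default_factory=list)
    best_epoch: int = 0
    epochs_run: int = 0
    stopping_reason: str = "not started"


class _PairTensors:
    """Pairs flattened into index arrays over the unique IWCs they touch.

    Weather windows are deduplicated by content so the GRU runs once per
    distinct window (windows are shared by every plant imaged on the
    same day in the same field).
    """

    def __init__(self, train_pairs, val_pairs):
        iwc_ids: dict[int, int] = {}
        iwcs = []
        for pair in list(train_pairs) + list(val_pairs):
            for iwc in (pair.first, pair.second):
                if id(iwc) not in iwc_ids:
                    iwc_ids[id(iwc)] = len(iwcs)
                    iwcs.append(iwc)
        for iwc in iwcs:
            if iwc.image is None or iwc.weather is None:
                raise ValidationError(
                    f"IWC {iwc.plant_id}@{iwc.capture_date} lacks image or weather"
                )
        self.images = preprocess_images(
            np.stack([iwc.image.pixels for iwc in iwcs])
        )
        raw_windows = [iwc.weather.matrix for iwc in iwcs]

        # stats from the training split only
        train_iwc_rows = sorted(
            {iwc_ids[id(iwc)] for p in train_pairs for iwc in (p.first, p.second)}
        )
        self.stats = WindowStats.fit([raw_windows[i] for i in train_iwc_rows])
        norm = np.stack(
            [normalize_window(w, self.stats) for w in raw_windows]
        ).astype(np.float32)
        keys = {}
        self.win_idx = np.empty(len(iwcs), dtype=np.int64)
        unique = []
        for i, w in enumerate(norm):
            key = w.tobytes()
            if key not in keys:
                keys[key] = len(unique)
                unique.append(w)
            self.win_idx[i] = keys[key]
        self.windows_u = np.stack(unique)

        def pair_rows(pairs):
            a = np.array([iwc_ids[id(p.first)] for p in pairs], dtype=np.int64)
            b = np.array([iwc_ids[id(p.second)] for p in pairs], dtype=np.int64)
            y = np.array([p.label.class_index for p in pairs], dtype=np.int64)
            return a, b, y

        self.train = pair_rows(train_pairs)
        self.val = pair_rows(val_pairs)


def _forward_pairs(model, data: _PairTensors, a, b, y, eps, n_classes):
    rows = np.concatenate([a, b])
    widx = data.win_idx[rows]
    u, inv = np.unique(widx, return_inverse=True)
    feats = model.extractor.forward_dedup(
        Tensor(data.images[rows]), Tensor(data.windows_u[u]), inv
    )
    v1 = feats[: len(a)]
    v2 = feats[len(a):]
    logits = model.head(v1, v2)
    loss = smoothed_cross_entropy(logits, y, eps, n_classes)
    return logits, loss


def f1_from_predictions(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int) -> float:
    """Binary: F1 of the positive class; ternary: macro F1."""
    from .fewshot import f1_score

    if n_classes == 2:
        tp = int(np.sum((y_pred == 1) & (y_true == 1)))
        fp = int(np.sum((y_pred == 1) & (y_true != 1)))
        fn = int(np.sum((y_pred != 1) & (y_true == 1)))
        return f1_score(tp, fp, fn)
    scores = []
    for c in range(n_classes):
        tp = int(np.sum((y_pred == c) & (y_true == c)))
        fp = int(np.sum((y_pred == c) & (y_true != c)))
        fn = int(np.sum((y_pred != c) & (y_true == c)))
        scores.append(f1_score(tp, fp, fn))
    return float(np.mean(scores))


def _evaluate(model, data, split, eps, n_classes, batch_size):
    a, b, y = split
    losses, preds = [], []
    with nn.no_grad():
        for lo in range(0, len(a), batch_size):
            sl = slice(lo, lo + batch_size)
            logits, loss = _forward_pairs(
                model, data, a[sl], b[sl], y[sl], eps, n_classes
            )
            losses.append(float(loss.data) * len(a[sl]))
            preds.append(np.argmax(logits.data, axis=1))
    y_pred = np.concatenate(preds)
    return float(np.sum(losses) / len(a)), f1_from_predictions(y, y_pred, n_classes)


def train_meta(
    model: SiameseComparator,
    train_pairs: list[IWCPair],
    val_pairs: list[IWCPair],
    config: TrainConfig,
) -> tuple[dict, TrainReport]:
    """Train extractor + head on fixed pair sets; early stop on EMA val F1.

    Returns ``(best, report)`` where ``best`` holds the raw and EMA
    parameter sets of the best epoch; the model is left loaded with the
    best EMA parameters.
    """
    if not train_pairs or not val_pairs:
        raise ValidationError("pair sets must be non-empty")
    n_classes = model.comp_spec.n_classes
    expected = 2 if config.scheme == BINARY else 3
    if n_classes != expected:
        raise ValidationError(
            f"head has {n_classes} classes but scheme {config.scheme!r} "
            f"needs {expected}"
        )
    data = _PairTensors(train_pairs, val_pairs)
    model.window_stats = data.stats
    params = model.parameters()
    report = TrainReport()
    best = {"raw": model.state(), "ema": model.state()}
    if config.epochs_max == 0:
        report.stopping_reason = "epochs_max reached"
        return best, report

    rng = np.random.Generator(np.random.PCG64(config.seed))
    opt = nn.Adam(
        params,
        lr=config.lr_max,
        weight_decay=config.weight_decay,
        amsgrad=config.amsgrad,
    )
    ema = model.state()
    a_tr, b_tr, y_tr = data.train
    steps_per_epoch = math.ceil(len(a_tr) / config.batch_size)
    total_steps = config.epochs_max * steps_per_epoch
    step = 0
    best_f1 = -np.inf
    since_improve = 0
    for epoch in range(1, config.epochs_max + 1):
        order = rng.permutation(len(a_tr))
        epoch_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            opt.lr = cosine_lr(step, total_steps, config.lr_max, config.lr_min)
            model.zero_grad()
            _, loss = _forward_pairs(
                model, data, a_tr[idx], b_tr[idx], y_tr[idx],
                config.label_smooth_eps, n_classes,
            )
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"divergent loss at epoch {epoch}, step {step}: {loss.data}"
                )
            loss.backward()
            opt.step()
            # decay warmup: early on the average tracks the parameters,
            # converging to the configured decay as steps accumulate
            decay = min(config.ema_decay, (1.0 + step) / (10.0 + step))
            ema = ema_update(ema, {k: p.data for k, p in params.items()}, decay)
            epoch_loss += float(loss.data) * len(idx)
            step += 1
        report.train_loss.append(epoch_loss / len(a_tr))

        _, val_f1_raw = _evaluate(
            model, data, data.val, config.label_smooth_eps, n_classes,
            config.batch_size,
        )
        report.val_f1_raw.append(val_f1_raw)
        raw_state = model.state()
        model.load_state(ema)
        val_loss, val_f1 = _evaluate(
            model, data, data.val, config.label_smooth_eps, n_classes,
            config.batch_size,
        )
        model.load_state(raw_state)
        report.val_loss.append(val_loss)
        report.val_f1.append(val_f1)
        report.epochs_run = epoch

        if val_f1 > best_f1:
            best_f1 = val_f1
            report.best_epoch = epoch
            best = {"raw": raw_state, "ema": {k: v.copy() for k, v in ema.items()}}
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= config.patience:
                report.stopping_reason = "early stopping (patience exhausted)"
                model.load_state(best["ema"])
                return best, report
    report.stopping_reason = "epochs_max reached"
    model.load_state(best["ema"])
    return best, report
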
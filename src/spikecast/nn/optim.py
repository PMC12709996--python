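"""Adam-family optimiser and exponential moving average of parameters."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Adam:
    """Adam with optional decoupled weight decay and AMSGrad.

    Both extensions default to off; they are the two stabilisations the
    comparator trainer exposes for its "adapted Adam" configuration.
    """

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
        amsgrad: bool = False,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.amsgrad = amsgrad
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.vmax = (
            {k: np.zeros_like(p.data) for k, p in params.items()} if amsgrad else None
        )

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            v_hat = self.v[k] / bc2
            if self.amsgrad:
                np.maximum(self.vmax[k], v_hat, out=self.vmax[k])
                v_hat = self.vmax[k]
            update = (self.m[k] / bc1) / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay:
                update = update + self.weight_decay * p.data
            p.data = p.data - self.lr * update

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def ema_update(
    ema_params: dict[str, np.ndarray],
    current_params: dict[str, np.ndarray],
    decay: float,
) -> dict[str, np.ndarray]:
    """One EMA step: ema <- decay * ema + (1 - decay) * current."""
    if set(ema_params) != set(current_params):
        raise ValueError("EMA and current parameter sets have different keys")
    out = {}
    for k, e in ema_params.items():
        c = np.asarray(current_params[k])
        if e.shape != c.shape:
            raise ValueError(f"shape mismatch for {k}: {e.shape} vs {c.shape}")
        out[k] = decay * e + (1.0 - decay) * c
    return out
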
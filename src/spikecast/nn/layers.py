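"""Neural-network building blocks on top of the autodiff engine.

Initialisation is Glorot-uniform and driven by an explicit
``numpy.random.Generator`` so every model build is reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, softmax, unbind


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Module:
    """Base class: a module owns named parameters and/or sub-modules."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                params[name] = value
            elif isinstance(value, Module):
                for sub, p in value.parameters().items():
                    params[f"{name}.{sub}"] = p
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, p in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = p
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.zero_grad()

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) - set(state)
        if missing:
            raise ValueError(f"missing parameters in state: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                )
            p.data = arr.copy()

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, in_dim, out_dim, (in_dim, out_dim)), True)
        self.b = Tensor(np.zeros(out_dim, dtype=np.float32), True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class GRU(Module):
    """Single-layer gated recurrent unit; returns the final hidden state.

    Update rule (reset gate r, update gate z, candidate n):
        h_t = (1 - z_t) * n_t + z_t * h_{t-1}
    """

    def __init__(self, in_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.Wx = Tensor(glorot(rng, in_dim, 3 * hidden_dim, (in_dim, 3 * hidden_dim)), True)
        self.Wh = Tensor(
            glorot(rng, hidden_dim, 3 * hidden_dim, (hidden_dim, 3 * hidden_dim)), True
        )
        self.bx = Tensor(np.zeros(3 * hidden_dim, dtype=np.float32), True)
        self.bh = Tensor(np.zeros(3 * hidden_dim, dtype=np.float32), True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 3:
            raise ValueError(f"GRU expects (batch, time, features), got {x.shape}")
        B, T, I = x.shape
        H = self.hidden_dim
        # project the whole sequence through the input weights in one matmul
        xp = x.reshape(B * T, I) @ self.Wx + self.bx
        steps = unbind(xp.reshape(B, T, 3 * H), axis=1)
        h = Tensor(np.zeros((B, H), dtype=np.float32))
        for t in range(T):
            xt = steps[t]
            hp = h @ self.Wh + self.bh
            r = (xt[:, :H] + hp[:, :H]).sigmoid()
            z = (xt[:, H : 2 * H] + hp[:, H : 2 * H]).sigmoid()
            n = (xt[:, 2 * H :] + r * hp[:, 2 * H :]).tanh()
            h = (1.0 - z) * n + z * h
        return h


class Conv3x3(Module):
    """3x3 same-padding convolution via an im2col matmul."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        fan_in, fan_out = in_ch * 9, out_ch * 9
        self.W = Tensor(glorot(rng, fan_in, fan_out, (in_ch * 9, out_ch)), True)
        self.b = Tensor(np.zeros(out_ch, dtype=np.float32), True)

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, Wd = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        pad_spec = ((0, 0), (0, 0), (1, 1), (1, 1))
        padded = np.pad(x.data, pad_spec)
        win = np.lib.stride_tricks.sliding_window_view(padded, (3, 3), axis=(2, 3))
        # (B, C, H, W, 3, 3) -> (B*H*W, C*9)
        cols_np = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, C * 9)
        cols_np = np.ascontiguousarray(cols_np)
        cols = Tensor._op(cols_np, (x,), None)

        def backward(g):
            gwin = g.reshape(B, H, Wd, C, 3, 3)
            gpad = np.zeros_like(padded)
            for di in range(3):
                for dj in range(3):
                    gpad[:, :, di : di + H, dj : dj + Wd] += gwin[
                        :, :, :, :, di, dj
                    ].transpose(0, 3, 1, 2)
            x._accumulate(gpad[:, :, 1 : 1 + H, 1 : 1 + Wd])

        cols._backward = backward
        out = cols @ self.W + self.b
        return out.reshape(B, H, Wd, self.out_ch).transpose(0, 3, 1, 2)


class MaxPool2x2(Module):
    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"MaxPool2x2 needs even spatial dims, got {H}x{W}")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        return xr.max(axis=-1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(dim, dtype=np.float32), True)
        self.beta = Tensor(np.zeros(dim, dtype=np.float32), True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).pow(0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Standard scaled dot-product self-attention over a short token axis."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"model dim {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads, self.head_dim = dim, n_heads, dim // n_heads
        self.Wq = Linear(dim, dim, rng)
        self.Wk = Linear(dim, dim, rng)
        self.Wv = Linear(dim, dim, rng)
        self.Wo = Linear(dim, dim, rng)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        return x.reshape(B, T, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        flat = x.reshape(B * T, D)
        q = self._split(self.Wq(flat).reshape(B, T, D), B, T)
        k = self._split(self.Wk(flat).reshape(B, T, D), B, T)
        v = self._split(self.Wv(flat).reshape(B, T, D), B, T)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        attn = softmax(scores, axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B * T, D)
        return self.Wo(ctx).reshape(B, T, D)


class TinyCNNBackbone(Module):
    """Small three-block convolutional backbone with a 1000-d output head.

    Serves as the desk-scale stand-in behind the image-backbone plug-in
    contract (any callable image -> 1000-d vector qualifies); the 1000-d
    output follows the ImageNet-classifier-head convention of the large
    pretrained backbones.
    """

    out_dim = 1000

    def __init__(self, rng: np.random.Generator, in_ch: int = 3):
        self.conv1 = Conv3x3(in_ch, 16, rng)
        self.conv2 = Conv3x3(16, 32, rng)
        self.conv3 = Conv3x3(32, 64, rng)
        self.pool = MaxPool2x2()
        self.head = Linear(64, 1000, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.pool(self.conv1(x).relu())
        x = self.pool(self.conv2(x).relu())
        x = self.pool(self.conv3(x).relu())
        # global average pool over the remaining spatial grid
        B, C = x.shape[0], x.shape[1]
        x = x.reshape(B, C, x.shape[2] * x.shape[3]).mean(axis=-1)
        return self.head(x)
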
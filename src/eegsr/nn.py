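"""Neural-network layers and optimization on top of the autodiff engine.

Convolutions use an im2col formulation (``numpy.lib.stride_tricks``); the
layout convention for signal tensors is ``(batch, channels, length)`` and for
sequence tensors fed to state-space blocks ``(batch, length, features)``.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._autodiff import Parameter, Tensor, concat, no_grad

__all__ = [
    "Module", "Linear", "Conv1d", "DepthwiseConv1d", "ZeroUpsample1d",
    "LayerNorm", "RMSNorm", "Dropout", "Embedding", "Sequential", "AdamW",
    "concat", "no_grad",
]


class Module:
    """Base class with recursive parameter discovery (torch-style)."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=key + "."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def modules(self):
        yield self
        for val in vars(self).values():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data[...] = state[k]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(_kaiming(rng, (d_in, d_out), d_in))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        self.weight = Parameter(rng.normal(0.0, 1.0, size=(n, dim)))

    def forward(self, idx) -> Tensor:
        return self.weight[np.asarray(idx, dtype=int)]


class Conv1d(Module):
    """Standard 1-D convolution on (B, C, L) tensors."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, causal: bool = False):
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, k), c_in * k))
        self.bias = Parameter(np.zeros(c_out))
        self.stride, self.padding, self.k, self.causal = stride, padding, k, causal

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        s, k = self.stride, self.k
        pl, pr = (k - 1, 0) if self.causal else (self.padding, self.padding)
        xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]  # (B,Cin,Lo,k)
        y = np.einsum("ock,bclk->bol", w.data, win, optimize=True) + b.data[:, None]
        L_in, L_out = x.data.shape[2], y.shape[2]

        def bw(g):
            w._accum(np.einsum("bol,bclk->ock", g, win, optimize=True))
            b._accum(g.sum(axis=(0, 2)))
            dwin = np.einsum("ock,bol->bclk", w.data, g, optimize=True)
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j:j + s * (L_out - 1) + 1:s] += dwin[:, :, :, j]
            x._accum(dxp[:, :, pl:pl + L_in])

        return Tensor._make(y, (x, w, b), bw)


class DepthwiseConv1d(Module):
    """Per-channel (grouped) 1-D convolution; optionally causal."""

    def __init__(self, channels: int, k: int, rng: np.random.Generator,
                 causal: bool = True, padding: int | None = None):
        self.weight = Parameter(_kaiming(rng, (channels, k), k))
        self.bias = Parameter(np.zeros(channels))
        self.k, self.causal = k, causal
        self.padding = (k - 1) // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        k = self.k
        pl, pr = (k - 1, 0) if self.causal else (self.padding, self.padding)
        xp = np.pad(x.data, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, k, axis=2)  # (B,C,Lo,k)
        y = np.einsum("ck,bclk->bcl", w.data, win, optimize=True) + b.data[:, None]
        L_in, L_out = x.data.shape[2], y.shape[2]

        def bw(g):
            w._accum(np.einsum("bcl,bclk->ck", g, win, optimize=True))
            b._accum(g.sum(axis=(0, 2)))
            dxp = np.zeros_like(xp)
            for j in range(k):
                dxp[:, :, j:j + L_out] += w.data[:, j][None, :, None] * g
            x._accum(dxp[:, :, pl:pl + L_in])

        return Tensor._make(y, (x, w, b), bw)


class ZeroUpsample1d(Module):
    """Insert ``stride - 1`` zeros between samples (transposed-conv expansion)."""

    def __init__(self, stride: int):
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        s = self.stride
        B, C, L = x.data.shape
        y = np.zeros((B, C, L * s))
        y[:, :, ::s] = x.data
        return Tensor._make(y, (x,), lambda g: x._accum(g[:, :, ::s]))


class LayerNorm(Module):
    """Normalize over a given axis (default: last)."""

    def __init__(self, dim: int, axis: int = -1, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.axis, self.eps, self.dim = axis, eps, dim

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=self.axis, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=self.axis, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        shape = [1] * x.ndim
        shape[self.axis] = self.dim
        return xn * self.gamma.reshape(shape) + self.beta.reshape(shape)


class RMSNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(dim))
        self.eps, self.dim = eps, dim

    def forward(self, x: Tensor) -> Tensor:
        ms = (x * x).mean(axis=-1, keepdims=True)
        return x / (ms + self.eps).sqrt() * self.gamma


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class AdamW:
    """AdamW with optional cosine learning-rate decay and gradient clipping."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4,
                 total_steps: int | None = None, lr_min: float = 1e-5,
                 clip_norm: float | None = 1.0):
        self.params = list(params)
        self.lr0, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.total_steps, self.lr_min, self.clip_norm = total_steps, lr_min, clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _lr(self) -> float:
        if not self.total_steps:
            return self.lr0
        frac = min(self.t / self.total_steps, 1.0)
        return self.lr_min + 0.5 * (self.lr0 - self.lr_min) * (1 + math.cos(math.pi * frac))

    def step(self) -> None:
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((p.grad ** 2).sum()) for p in self.params if p.grad is not None))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        lr = self._lr()
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
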
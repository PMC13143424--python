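"""Selective state-space (Mamba) backbone with bidirectional fusion.

The recurrence is the canonical selective SSM: input-dependent step sizes
``Delta``, input/output mixings ``B``/``C`` and a diagonal decay ``A``,
discretized by zero-order hold on ``A`` (``exp(Delta A)``) and Euler on
``B`` (``Delta B``)::

    h_t = exp(Delta_t A) * h_{t-1} + (Delta_t B_t) u_t,   h_0 = 0
    y_t = C_t . h_t + D * u_t

Two block flavours are provided: version 1 (per-channel ``A`` over the full
state) and version 2 (multi-head scalar ``A`` with a post-SSM normalization,
the state-space-duality style block).  Both run the same sequential O(L)
scan — correctness over speed; no fused/parallel kernels.

The bidirectional layer runs M stacked blocks forward and on the
time-reversed sequence, refines each stream with a depthwise causal k=3
convolution (causal in the stream's own direction), and fuses by element-wise
addition.  Layers stack with a convolutional (k=3) skip path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._autodiff import Parameter, Tensor
from .nn import Conv1d, DepthwiseConv1d, Linear, Module, RMSNorm

__all__ = [
    "MambaBlockConfig", "BiMambaStackConfig", "selective_scan",
    "MambaBlock", "BiMambaResConvLayer", "BiMambaStack",
]

#: Global counter of scan recurrence steps, for complexity instrumentation.
SCAN_STEP_COUNTER = {"steps": 0}


@dataclass(frozen=True)
class MambaBlockConfig:
    version: int = 1
    d_model: int = 128
    d_state: int = 8
    d_conv: int = 3
    expand: int = 2
    n_heads: int = 4  # version 2 only

    def __post_init__(self):
        if self.version not in (1, 2):
            raise ValueError("version must be 1 or 2")
        if self.d_conv < 1:
            raise ValueError("d_conv must be >= 1")
        if self.version == 2 and (self.d_model * self.expand) % self.n_heads != 0:
            raise ValueError("d_model * expand must be divisible by n_heads")

    @property
    def d_inner(self) -> int:
        return self.d_model * self.expand


@dataclass(frozen=True)
class BiMambaStackConfig:
    n_layers: int = 2
    n_blocks_per_direction: int = 2
    skip_kernel: int = 3

    def __post_init__(self):
        if self.n_layers < 1 or self.n_blocks_per_direction < 1:
            raise ValueError("n_layers and n_blocks_per_direction must be >= 1")


def selective_scan(u: Tensor, delta: Tensor, A: Tensor, Bmat: Tensor,
                   Cmat: Tensor, D: Tensor) -> Tensor:
    """Run the selective recurrence left-to-right in a single O(L) pass.

    Shapes: ``u``/``delta`` (B, L, E); ``A`` (E, N); ``Bmat``/``Cmat``
    (B, L, N); ``D`` (E,).  ``delta`` must be positive (enforce upstream with
    a softplus).  Differentiable in all six arguments via an analytic
    backward-through-time pass.
    """
    u, delta, A, Bmat, Cmat, D = map(Tensor._lift, (u, delta, A, Bmat, Cmat, D))
    ud, dd, Ad, Bd, Cd, Dd = (t.data for t in (u, delta, A, Bmat, Cmat, D))
    Bb, L, E = ud.shape
    N = Ad.shape[1]
    a = np.exp(dd[..., None] * Ad[None, None])  # (B, L, E, N)
    hs = np.empty((Bb, L, E, N))
    h = np.zeros((Bb, E, N))
    for t in range(L):
        h = a[:, t] * h + (dd[:, t, :, None] * Bd[:, t, None, :]) * ud[:, t, :, None]
        if not np.all(np.isfinite(h)):
            raise FloatingPointError(f"non-finite scan state at step {t}")
        hs[:, t] = h
    SCAN_STEP_COUNTER["steps"] += L
    y = np.einsum("blen,bln->ble", hs, Cd, optimize=True) + Dd * ud

    def bw(gy):
        Cmat._accum(np.einsum("ble,blen->bln", gy, hs, optimize=True))
        D._accum(np.einsum("ble,ble->e", gy, ud, optimize=True))
        du = gy * Dd
        dA = np.zeros_like(Ad)
        ddelta = np.zeros_like(dd)
        dB = np.zeros_like(Bd)
        gh = np.zeros((Bb, E, N))
        for t in range(L - 1, -1, -1):
            gh = gh + gy[:, t, :, None] * Cd[:, t, None, :]
            h_prev = hs[:, t - 1] if t > 0 else 0.0
            da = gh * h_prev  # d loss / d a_t
            dA += (da * a[:, t] * dd[:, t, :, None]).sum(axis=0)
            ddelta[:, t] = ((da * a[:, t]) * Ad[None]).sum(axis=-1) \
                + (gh * Bd[:, t, None, :]).sum(axis=-1) * ud[:, t]
            dB[:, t] = (gh * dd[:, t, :, None] * ud[:, t, :, None]).sum(axis=1)
            du[:, t] += (gh * dd[:, t, :, None] * Bd[:, t, None, :]).sum(axis=-1)
            gh = a[:, t] * gh
        u._accum(du)
        delta._accum(ddelta)
        A._accum(dA)
        Bmat._accum(dB)

    return Tensor._make(y, (u, delta, A, Bmat, Cmat, D), bw)


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    return y + np.log(-np.expm1(-y))


class MambaBlock(Module):
    """One Mamba block: in-projection, causal depthwise conv, SiLU-gated scan.

    Version 2 additionally normalizes the scan output before gating and uses
    one scalar decay per head (shared across that head's channels and state).
    """

    def __init__(self, cfg: MambaBlockConfig, rng: np.random.Generator):
        self.cfg = cfg
        D, E, N = cfg.d_model, cfg.d_inner, cfg.d_state
        self.in_proj = Linear(D, 2 * E, rng)
        self.conv = DepthwiseConv1d(E, cfg.d_conv, rng, causal=True)
        self.dt_rank = max(1, math.ceil(D / 16))
        self.x_proj = Linear(E, self.dt_rank + 2 * N, rng, bias=False)
        self.dt_proj = Linear(self.dt_rank, E, rng)
        # bias chosen so softplus(bias) spans [1e-3, 0.1] — stable step sizes
        dt = np.exp(rng.uniform(math.log(1e-3), math.log(0.1), size=E))
        self.dt_proj.bias.data[...] = _inv_softplus(dt)
        self.dt_proj.weight.data *= 0.1
        if cfg.version == 1:
            self.A_log = Parameter(np.log(np.tile(np.arange(1, N + 1, dtype=float), (E, 1))))
            self.norm = None
        else:
            self.A_log = Parameter(np.log(rng.uniform(1.0, 16.0, size=cfg.n_heads)))
            self.norm = RMSNorm(E)
            self._head_of_channel = np.repeat(np.arange(cfg.n_heads), E // cfg.n_heads)
        self.D_param = Parameter(np.ones(E))
        self.out_proj = Linear(E, D, rng, bias=False)

    def _A(self) -> Tensor:
        N = self.cfg.d_state
        if self.cfg.version == 1:
            return -self.A_log.exp()
        per_channel = self.A_log[self._head_of_channel]  # (E,)
        return -(per_channel.exp().reshape(-1, 1) * Tensor(np.ones((1, N))))

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        E, N, R = cfg.d_inner, cfg.d_state, self.dt_rank
        xz = self.in_proj(x)  # (B, L, 2E)
        sl = (slice(None), slice(None))
        xb, z = xz[sl + (slice(0, E),)], xz[sl + (slice(E, 2 * E),)]
        xb = self.conv(xb.transpose(0, 2, 1)).transpose(0, 2, 1).silu()
        proj = self.x_proj(xb)
        dt = proj[sl + (slice(0, R),)]
        Bmat = proj[sl + (slice(R, R + N),)]
        Cmat = proj[sl + (slice(R + N, R + 2 * N),)]
        delta = self.dt_proj(dt).softplus()
        y = selective_scan(xb, delta, self._A(), Bmat, Cmat, self.D_param)
        if self.norm is not None:
            y = self.norm(y)
        y = y * z.silu()
        return self.out_proj(y)


def _conv_over_time(conv: Module, x: Tensor) -> Tensor:
    """Apply a (B, C, L) convolution to a (B, L, D) sequence tensor."""
    return conv(x.transpose(0, 2, 1)).transpose(0, 2, 1)


class BiMambaResConvLayer(Module):
    """Bidirectional layer: forward and time-reversed block stacks, each
    refined by a depthwise causal k=3 conv, fused by element-wise addition.

    ``tied_directions`` shares parameters between the two streams; with tied
    weights the layer commutes with time reversal (used as a test
    invariant), with separate weights (the default) each direction learns
    its own dynamics.
    """

    def __init__(self, block_cfg: MambaBlockConfig, n_blocks: int,
                 rng: np.random.Generator, tied_directions: bool = False):
        D = block_cfg.d_model
        self.fwd_blocks = [MambaBlock(block_cfg, rng) for _ in range(n_blocks)]
        self.fwd_conv = DepthwiseConv1d(D, 3, rng, causal=True)
        if tied_directions:
            self.bwd_blocks = self.fwd_blocks
            self.bwd_conv = self.fwd_conv
        else:
            self.bwd_blocks = [MambaBlock(block_cfg, rng) for _ in range(n_blocks)]
            self.bwd_conv = DepthwiseConv1d(D, 3, rng, causal=True)
        self.tied = tied_directions

    def named_parameters(self, prefix: str = ""):
        params = super().named_parameters(prefix)
        if self.tied:  # drop aliased entries
            seen, out = set(), []
            for k, p in params:
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append((k, p))
            return out
        return params

    def _stream(self, x: Tensor, blocks, conv) -> Tensor:
        for blk in blocks:
            x = blk(x)
        return _conv_over_time(conv, x)

    def forward(self, x: Tensor) -> Tensor:
        fwd = self._stream(x, self.fwd_blocks, self.fwd_conv)
        bwd = self._stream(x.flip(1), self.bwd_blocks, self.bwd_conv).flip(1)
        return fwd + bwd


class BiMambaStack(Module):
    """N bidirectional layers with convolutional (k=3) skip connections:
    ``x^(i+1) = BiMamba(x^(i)) + proj(x^(i))``."""

    def __init__(self, stack_cfg: BiMambaStackConfig, block_cfg: MambaBlockConfig,
                 rng: np.random.Generator, tied_directions: bool = False):
        D = block_cfg.d_model
        self.stack_cfg, self.block_cfg = stack_cfg, block_cfg
        self.layers = [
            BiMambaResConvLayer(block_cfg, stack_cfg.n_blocks_per_direction,
                                rng, tied_directions=tied_directions)
            for _ in range(stack_cfg.n_layers)
        ]
        self.projs = [
            Conv1d(D, D, stack_cfg.skip_kernel, rng,
                   padding=(stack_cfg.skip_kernel - 1) // 2)
            for _ in range(stack_cfg.n_layers)
        ]

    def forward(self, x: Tensor) -> Tensor:
        for layer, proj in zip(self.layers, self.projs):
            x = layer(x) + _conv_over_time(proj, x)
        return x
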
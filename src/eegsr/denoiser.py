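"""Encoder–bottleneck–decoder reconstruction networks.

Two operating modes share one trunk:

* regression — the network maps the naively upsampled low-resolution signal
  (HR-shaped, zero-padded channels or linearly interpolated time) directly
  to the high-resolution signal;
* diffusion denoiser — the network additionally receives the noisy signal
  ``x_t`` (channel-concatenated with the upsampled LR stream when LR
  conditioning is on) and a timestep embedding, and predicts either the
  clean signal or the injected noise depending on the schedule's prediction
  type.

Conditioning streams (upsampled LR, electrode-position embeddings, class
label) are individually switchable, which makes the four-way conditioning
ablation a pure configuration matter.  The bottleneck is either the
bidirectional Mamba stack or a plain convolutional stack (the ablation
variant); swapping it changes no encoder/decoder parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .nn import (Conv1d, Dropout, Embedding, LayerNorm, Linear, Module,
                 ZeroUpsample1d, concat)
from .ssm import BiMambaStack, BiMambaStackConfig, MambaBlockConfig

__all__ = [
    "ConditioningBundle", "ModelConfig", "sinusoidal_embedding",
    "TimestepEmbedding", "PositionEmbedding", "LabelEmbedding",
    "ReconstructionNet", "model_summary",
]

NULL_LABEL = -1  # reserved id mapping to the unconditional label embedding


@dataclass
class ConditioningBundle:
    """Conditioning inputs for one batch.

    ``lr_up``: HR-shaped (B, C, L) naive upsampling of the LR signal, or None.
    ``ranks``/``coords``: per-HR-channel montage identity, or None.
    ``label``: (B,) class ids (NULL_LABEL for unconditional), or None.
    ``timestep``: (B,) diffusion step indices, or None (regression).
    """

    lr_up: np.ndarray | None = None
    ranks: np.ndarray | None = None
    coords: np.ndarray | None = None
    label: np.ndarray | None = None
    timestep: np.ndarray | None = None


@dataclass(frozen=True)
class ModelConfig:
    hr_channels: int = 64
    hr_samples: int = 320
    base_width: int = 64
    depth: int = 2
    bottleneck: str = "bimamba"  # or "conv"
    block: MambaBlockConfig = field(default_factory=MambaBlockConfig)
    stack: BiMambaStackConfig = field(default_factory=BiMambaStackConfig)
    cond_lr: bool = True
    cond_positions: bool = False
    cond_label: bool = False
    n_classes: int = 2
    dropout: float = 0.1
    emb_dim: int = 32
    #: add the (HR-shaped) network input back onto the output — residual
    #: guidance from the upsampled LR signal; the trunk learns corrections
    input_skip: bool = True

    def __post_init__(self):
        if self.hr_samples % (2 ** self.depth) != 0:
            raise ValueError(
                f"hr_samples ({self.hr_samples}) must be divisible by "
                f"2^depth ({2 ** self.depth})")
        if self.bottleneck not in ("bimamba", "conv"):
            raise ValueError(f"unknown bottleneck {self.bottleneck!r}")

    @property
    def bottleneck_width(self) -> int:
        return self.base_width * 2 ** self.depth


def sinusoidal_embedding(t, dim: int) -> np.ndarray:
    """Deterministic sinusoidal encoding of integer timesteps, shape (B, dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    half = dim // 2
    freqs = np.exp(-math.log(10000.0) * np.arange(half) / max(half - 1, 1))
    args = t[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.pad(emb, ((0, 0), (0, 1)))
    return emb


class TimestepEmbedding(Module):
    """Sinusoidal encoding followed by a small learned map."""

    def __init__(self, dim: int, rng: np.random.Generator, max_t: int | None = None):
        self.proj = Linear(dim, dim, rng)
        self.dim, self.max_t = dim, max_t

    def forward(self, t) -> Tensor:
        t = np.atleast_1d(np.asarray(t, dtype=int))
        if np.any(t < 0) or (self.max_t is not None and np.any(t >= self.max_t)):
            raise ValueError(f"timestep out of range [0, {self.max_t})")
        return self.proj(Tensor(sinusoidal_embedding(t, self.dim))).silu()


class PositionEmbedding(Module):
    """Learnable rank-based table plus a linear map of the 3-D coordinates."""

    def __init__(self, n_channels: int, dim: int, rng: np.random.Generator):
        self.table = Embedding(n_channels, dim, rng)
        self.coord_proj = Linear(3, dim, rng, bias=False)
        self.n_channels = n_channels

    def forward(self, ranks, coords) -> Tensor:
        ranks = np.asarray(ranks, dtype=int)
        if len(np.unique(ranks)) != len(ranks):
            raise ValueError("electrode rank collision in position embedding")
        return self.table(ranks) + self.coord_proj(Tensor(np.asarray(coords, dtype=float)))


class LabelEmbedding(Module):
    """Class-label table; the reserved null id selects the unconditional row."""

    def __init__(self, n_classes: int, dim: int, rng: np.random.Generator):
        self.table = Embedding(n_classes + 1, dim, rng)
        self.n_classes = n_classes

    def forward(self, label) -> Tensor:
        label = np.atleast_1d(np.asarray(label, dtype=int))
        if np.any((label < 0) & (label != NULL_LABEL)) or np.any(label >= self.n_classes):
            raise ValueError(f"label out of range [0, {self.n_classes})")
        idx = np.where(label == NULL_LABEL, self.n_classes, label)
        return self.table(idx)


class _ConvBottleneck(Module):
    """Ablation variant: Conv1D / norm / LeakyReLU / Dropout, twice."""

    def __init__(self, width: int, dropout: float, rng: np.random.Generator):
        self.conv1 = Conv1d(width, width, 3, rng, padding=1)
        self.norm1 = LayerNorm(width, axis=1)
        self.drop1 = Dropout(dropout, rng)
        self.conv2 = Conv1d(width, width, 3, rng, padding=1)
        self.norm2 = LayerNorm(width, axis=1)
        self.drop2 = Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.drop1(self.norm1(self.conv1(x)).leaky_relu(0.2))
        return self.drop2(self.norm2(self.conv2(x)).leaky_relu(0.2))


class _BiMambaBottleneck(Module):
    def __init__(self, width: int, cfg: ModelConfig, rng: np.random.Generator):
        self.inp = Linear(width, cfg.block.d_model, rng)
        self.stack = BiMambaStack(cfg.stack, cfg.block, rng)
        self.out = Linear(cfg.block.d_model, width, rng)

    def forward(self, x: Tensor) -> Tensor:
        seq = x.transpose(0, 2, 1)  # (B, L, width)
        seq = self.out(self.stack(self.inp(seq)))
        return seq.transpose(0, 2, 1)


class ReconstructionNet(Module):
    """The shared encoder–bottleneck–decoder trunk.

    ``diffusion=True`` adds the noisy-input stream and timestep embedding;
    otherwise the network is the deterministic regression model.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 diffusion: bool = False, max_t: int | None = None):
        self.cfg = cfg
        self.diffusion = diffusion
        C, W, depth = cfg.hr_channels, cfg.base_width, cfg.depth
        c_in = C
        if diffusion:
            c_in = C * 2 if cfg.cond_lr else C
        self.stem = Conv1d(c_in, W, 3, rng, padding=1)
        self.enc = [Conv1d(W * 2 ** i, W * 2 ** (i + 1), 4, rng, stride=2, padding=1)
                    for i in range(depth)]
        Wb = cfg.bottleneck_width
        if cfg.bottleneck == "bimamba":
            self.bottleneck = _BiMambaBottleneck(Wb, cfg, rng)
        else:
            self.bottleneck = _ConvBottleneck(Wb, cfg.dropout, rng)
        self.dec_up = [ZeroUpsample1d(2) for _ in range(depth)]
        self.dec = [Conv1d(W * 2 ** (i + 1), W * 2 ** i, 3, rng, padding=1)
                    for i in reversed(range(depth))]
        self.head = Conv1d(W, C, 3, rng, padding=1)
        if cfg.cond_positions:
            self.pos_emb = PositionEmbedding(C, cfg.emb_dim, rng)
            self.pos_out = Linear(cfg.emb_dim, 1, rng)
        if cfg.cond_label:
            self.label_emb = LabelEmbedding(cfg.n_classes, cfg.emb_dim, rng)
            self.label_out = Linear(cfg.emb_dim, Wb, rng)
        if diffusion:
            self.t_emb = TimestepEmbedding(cfg.emb_dim, rng, max_t=max_t)
            self.t_out = [Linear(cfg.emb_dim, W * 2 ** (i + 1), rng)
                          for i in range(depth)]

    def forward(self, x, cond: ConditioningBundle | None = None) -> Tensor:
        cfg = self.cfg
        cond = cond or ConditioningBundle()
        x = Tensor._lift(x)
        skip = None
        if cfg.input_skip:
            if self.diffusion:
                if cfg.cond_lr and cond.lr_up is not None:
                    skip = Tensor._lift(cond.lr_up)
            else:
                skip = x
        if self.diffusion:
            if cond.timestep is None:
                raise ValueError("diffusion mode requires cond.timestep")
            if cfg.cond_lr:
                if cond.lr_up is None:
                    raise ValueError("cond_lr is on but cond.lr_up is missing")
                lr_up = Tensor._lift(cond.lr_up)
                lr_up = self._add_position_bias(lr_up, cond)
                x = concat([x, lr_up], axis=1)
        else:
            x = self._add_position_bias(x, cond)
        h = self.stem(x).silu()
        temb = None
        if self.diffusion:
            temb = self.t_emb(cond.timestep)  # (B, emb)
        for i, enc in enumerate(self.enc):
            h = enc(h).silu()
            if temb is not None:
                bias = self.t_out[i](temb)  # (B, width)
                h = h + bias.reshape(bias.shape[0], bias.shape[1], 1)
        if cfg.cond_label and cond.label is not None:
            lab = self.label_out(self.label_emb(cond.label))  # (B, Wb)
            h = h + lab.reshape(lab.shape[0], lab.shape[1], 1)
        h = self.bottleneck(h)
        for up, dec in zip(self.dec_up, self.dec):
            h = dec(up(h)).silu()
        out = self.head(h)
        return out + skip if skip is not None else out

    def _add_position_bias(self, stream: Tensor, cond: ConditioningBundle) -> Tensor:
        if not self.cfg.cond_positions or cond.ranks is None:
            return stream
        emb = self.pos_emb(cond.ranks, cond.coords)  # (C, emb)
        bias = self.pos_out(emb)  # (C, 1)
        return stream + bias.reshape(1, -1, 1)


def model_summary(net: ReconstructionNet) -> dict:
    """Parameter counts, total and per top-level submodule."""
    per_module: dict[str, int] = {}
    for name, p in net.named_parameters():
        top = name.split(".")[0]
        per_module[top] = per_module.get(top, 0) + p.data.size
    return {"total": net.n_parameters(), "per_module": per_module}
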
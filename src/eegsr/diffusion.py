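"""Denoising-diffusion machinery: schedule, noising, objective, samplers.

The schedule follows the squared-cosine ("squaredcos_cap_v2") shape whose
per-step variances are affinely rescaled to the configured endpoints
(beta_min=1e-4, beta_max=0.015 over T=1000 steps), sample clipping disabled.
The default prediction type is "sample" (the denoiser outputs the clean
signal directly); "epsilon" (noise prediction) is available as an option.

Sampling supports the one-step strategy — initialize at the maximum
timestep from noise, optionally biased by the naively upsampled LR signal,
and call the denoiser exactly once — alongside reference multi-step DDPM
(ancestral) and DDIM (deterministic) recursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor
from .denoiser import ConditioningBundle, ReconstructionNet

__all__ = [
    "NoiseSchedule", "SamplerSpec", "make_schedule", "add_noise",
    "training_step", "one_step_sample", "multi_step_sample", "CountingDenoiser",
]


@dataclass(frozen=True)
class NoiseSchedule:
    T: int
    betas: np.ndarray
    prediction_type: str = "sample"  # or "epsilon"
    clip_samples: bool = False
    alphas: np.ndarray = field(default=None)
    alpha_bars: np.ndarray = field(default=None)

    def __post_init__(self):
        betas = np.asarray(self.betas, dtype=float)
        object.__setattr__(self, "betas", betas)
        object.__setattr__(self, "alphas", 1.0 - betas)
        object.__setattr__(self, "alpha_bars", np.cumprod(1.0 - betas))
        if self.prediction_type not in ("sample", "epsilon"):
            raise ValueError(f"unknown prediction type {self.prediction_type!r}")
        if len(betas) != self.T:
            raise ValueError("betas length must equal T")
        if np.any(betas <= 0) or np.any(betas >= 1):
            raise ValueError("betas must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {"T": self.T, "betas": self.betas.tolist(),
                "prediction_type": self.prediction_type,
                "clip_samples": self.clip_samples}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        return cls(T=d["T"], betas=np.asarray(d["betas"]),
                   prediction_type=d["prediction_type"],
                   clip_samples=d["clip_samples"])


@dataclass(frozen=True)
class SamplerSpec:
    mode: str = "one_step"  # one_step | ddpm | ddim
    n_steps: int = 50  # multi-step only
    init: str = "noise_plus_upsampled_lr"  # or "noise"
    init_noise_scale: float = 1.0

    def __post_init__(self):
        if self.mode not in ("one_step", "ddpm", "ddim"):
            raise ValueError(f"unknown sampler mode {self.mode!r}")
        if self.init not in ("noise", "noise_plus_upsampled_lr"):
            raise ValueError(f"unknown sampler init {self.init!r}")


def make_schedule(T: int = 1000, beta_min: float = 1e-4, beta_max: float = 0.015,
                  prediction_type: str = "sample") -> NoiseSchedule:
    """Squared-cosine beta schedule rescaled affinely to [beta_min, beta_max].

    The squared-cosine cumulative curve (offset s=0.008) fixes the *shape*:
    its per-step decay profile ``1 - abar_cos`` is mapped affinely onto the
    configured beta range, so ``min(beta) = beta_min`` and ``max(beta) =
    beta_max`` exactly while betas grow along the cosine-family S-curve.
    (Rescaling the raw capped per-step cosine betas instead would let their
    near-1 terminal values dominate the affine map and leave the terminal
    cumulative product far from zero.)  Cumulative products are recomputed
    from the rescaled betas.
    """
    if not (0 < beta_min < beta_max < 1):
        raise ValueError("need 0 < beta_min < beta_max < 1")
    s = 0.008
    tt = np.arange(T + 1) / T
    abar = np.cos((tt + s) / (1 + s) * np.pi / 2) ** 2
    abar = abar / abar[0]
    shape = 1.0 - abar[1:]
    shape = (shape - shape.min()) / (shape.max() - shape.min())
    scaled = beta_min + (beta_max - beta_min) * shape
    return NoiseSchedule(T=T, betas=scaled, prediction_type=prediction_type)


def _gather(arr: np.ndarray, t, like: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=int)
    vals = arr[t]
    return vals.reshape((-1,) + (1,) * (like.ndim - 1)) if t.ndim else vals


def add_noise(x0: np.ndarray, eps: np.ndarray, t, schedule: NoiseSchedule) -> np.ndarray:
    """Forward marginal ``x_t = sqrt(abar_t) x0 + sqrt(1 - abar_t) eps``."""
    t_arr = np.asarray(t, dtype=int)
    if np.any(t_arr < 0) or np.any(t_arr >= schedule.T):
        raise ValueError(f"timestep out of range [0, {schedule.T})")
    ab = _gather(schedule.alpha_bars, t_arr, np.asarray(x0))
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * eps


def training_step(batch: dict, net: ReconstructionNet, schedule: NoiseSchedule,
                  rng: np.random.Generator, bias_high_t: bool = False) -> Tensor:
    """One diffusion training objective evaluation (loss Tensor, pre-backward).

    ``batch`` holds ``hr`` (B, C, L) and optionally ``lr_up``, ``ranks``,
    ``coords``, ``label``.  Timesteps are uniform over [0, T); the optional
    high-t bias draws t with density increasing toward T (exposing the model
    to maximum-noise regimes), off by default.
    """
    hr = np.asarray(batch["hr"], dtype=float)
    B = hr.shape[0]
    if bias_high_t:
        t = np.minimum((schedule.T * rng.random(B) ** 0.25).astype(int), schedule.T - 1)
    else:
        t = rng.integers(0, schedule.T, size=B)
    eps = rng.standard_normal(hr.shape)
    x_t = add_noise(hr, eps, t, schedule)
    cond = ConditioningBundle(lr_up=batch.get("lr_up"), ranks=batch.get("ranks"),
                              coords=batch.get("coords"), label=batch.get("label"),
                              timestep=t)
    pred = net(x_t, cond)
    target = hr if schedule.prediction_type == "sample" else eps
    diff = pred - Tensor(target)
    loss = (diff * diff).mean()
    if not np.isfinite(loss.data):
        raise FloatingPointError(f"non-finite diffusion loss at timesteps {t}")
    return loss


class CountingDenoiser:
    """Wrap a denoise callable and count its invocations.

    The callable maps ``(x_t, cond, t) -> prediction`` as numpy arrays; the
    sampler contracts (exactly one call for one-step, exactly n_steps for
    multi-step) are asserted against this counter.
    """

    def __init__(self, fn):
        self.fn = fn
        self.calls = 0
        self.last_t = None

    def __call__(self, x_t, cond, t):
        self.calls += 1
        self.last_t = np.asarray(t)
        return np.asarray(self.fn(x_t, cond, t))


def _to_x0(pred: np.ndarray, x_t: np.ndarray, ab_t: float,
           schedule: NoiseSchedule) -> np.ndarray:
    if schedule.prediction_type == "sample":
        return pred
    return (x_t - np.sqrt(1.0 - ab_t) * pred) / np.sqrt(ab_t)


def one_step_sample(lr_up: np.ndarray, cond: ConditioningBundle, model,
                    schedule: NoiseSchedule, spec: SamplerSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Single-call reconstruction from the maximum timestep.

    ``x_init = sigma * eps`` (plus the upsampled LR signal when the init is
    LR-biased); the denoiser is called exactly once at ``t = T - 1`` and its
    clean-signal prediction is returned without clipping.
    """
    if spec.mode != "one_step":
        raise ValueError("spec.mode must be 'one_step'")
    counter = model if isinstance(model, CountingDenoiser) else CountingDenoiser(model)
    lr_up = np.asarray(lr_up, dtype=float)
    x = spec.init_noise_scale * rng.standard_normal(lr_up.shape)
    if spec.init == "noise_plus_upsampled_lr":
        x = x + lr_up
    t = schedule.T - 1
    batch = x.shape[0] if x.ndim == 3 else 1
    pred = counter(x, cond, np.full(batch, t, dtype=int))
    if counter.calls != 1:
        raise RuntimeError(
            f"one-step sampling contract violated: {counter.calls} denoiser calls")
    return _to_x0(pred, x, schedule.alpha_bars[t], schedule)


def multi_step_sample(lr_up: np.ndarray, cond: ConditioningBundle, model,
                      schedule: NoiseSchedule, spec: SamplerSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Reference multi-step reverse recursion (DDPM ancestral or DDIM, eta=0).

    Uses a strided, strictly decreasing timestep subsequence of length
    ``spec.n_steps``; the denoiser's prediction is converted to an implicit
    noise estimate at every step.
    """
    if spec.mode not in ("ddpm", "ddim"):
        raise ValueError("spec.mode must be 'ddpm' or 'ddim'")
    if not (1 <= spec.n_steps <= schedule.T):
        raise ValueError(f"n_steps must be in [1, {schedule.T}]")
    ts = np.unique(np.linspace(0, schedule.T - 1, spec.n_steps).round().astype(int))[::-1]
    if len(ts) != spec.n_steps:
        raise ValueError(f"invalid stride: {spec.n_steps} steps collapse to {len(ts)}")
    counter = model if isinstance(model, CountingDenoiser) else CountingDenoiser(model)
    lr_up = np.asarray(lr_up, dtype=float)
    x = spec.init_noise_scale * rng.standard_normal(lr_up.shape)
    if spec.init == "noise_plus_upsampled_lr":
        x = x + lr_up
    eta = 1.0 if spec.mode == "ddpm" else 0.0
    batch = x.shape[0] if x.ndim == 3 else 1
    for i, t in enumerate(ts):
        ab_t = schedule.alpha_bars[t]
        ab_prev = schedule.alpha_bars[ts[i + 1]] if i + 1 < len(ts) else 1.0
        pred = counter(x, cond, np.full(batch, t, dtype=int))
        x0_hat = _to_x0(pred, x, ab_t, schedule)
        eps_hat = (x - np.sqrt(ab_t) * x0_hat) / np.sqrt(1.0 - ab_t)
        sigma = eta * np.sqrt((1 - ab_prev) / (1 - ab_t)) * np.sqrt(1 - ab_t / ab_prev)
        dir_coeff = np.sqrt(np.clip(1.0 - ab_prev - sigma ** 2, 0.0, None))
        x = np.sqrt(ab_prev) * x0_hat + dir_coeff * eps_hat
        if sigma > 0 and i + 1 < len(ts):
            x = x + sigma * rng.standard_normal(x.shape)
    if counter.calls != spec.n_steps:
        raise RuntimeError(
            f"multi-step sampling used {counter.calls} calls, expected {spec.n_steps}")
    return x
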
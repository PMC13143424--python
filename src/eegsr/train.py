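"""Training/evaluation orchestration over window lists and ablation grids.

Thin wrappers around the estimators: build the degradation task from a
montage and factor, train on window splits, evaluate the full metric suite
on held-out windows, and sweep the one-axis-at-a-time ablation grids
(component presence, backbone hyperparameters, conditioning streams,
sampling initialization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .estimators import BiMambaRegressor, DiffusionSuperResolver, upsample_batch
from .metrics import evaluate_pair
from .montage import Montage, select_lr_subset
from .preprocess import spline_upsample_baseline, degrade_spatial, degrade_temporal
from .windows import EEGWindow, SRTaskSpec, stack_windows

__all__ = ["TrainConfig", "AblationGrid", "make_task", "degrade_batch",
           "train_model", "evaluate_model", "run_ablation",
           "baseline_reconstructions"]


@dataclass
class TrainConfig:
    """Optimization settings (AdamW with cosine decay, early stopping)."""

    epochs: int = 30  # 50 for diffusion by convention
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    patience: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs must be >= 1 and learning_rate > 0")


@dataclass
class AblationGrid:
    """One-axis-at-a-time sweep; all other settings stay at baseline."""

    axis: str
    values: list = field(default_factory=list)

    _AXES = ("presence", "mamba_version", "d_model", "d_state", "n_blocks",
             "n_layers", "conditioning", "sampling_init")

    def __post_init__(self):
        if self.axis not in self._AXES:
            raise ValueError(f"unknown ablation axis {self.axis!r}; "
                             f"choose from {self._AXES}")
        if not self.values:
            self.values = _default_values(self.axis)


def _default_values(axis: str) -> list:
    return {
        "presence": [(False, False), (False, True), (True, False), (True, True)],
        "mamba_version": [1, 2],
        "d_model": [32, 64, 128],
        "d_state": [8, 16],
        "n_blocks": [1, 2, 3],
        "n_layers": [1, 2],
        "conditioning": ["none", "lr", "lr+pos", "lr+pos+label"],
        "sampling_init": ["noise", "noise_plus_upsampled_lr"],
    }[axis]


def make_task(montage: Montage, mode: str, factor: int,
              hr_rate: float | None = None) -> SRTaskSpec:
    """Build the degradation task for a montage: farthest-point channel subset
    (spatial) or decimated rate (temporal)."""
    if mode == "spatial":
        return SRTaskSpec(mode="spatial", factor=factor,
                          lr_channel_indices=select_lr_subset(montage, factor),
                          hr_channels=len(montage))
    if hr_rate is None:
        raise ValueError("temporal task needs hr_rate")
    return SRTaskSpec(mode="temporal", factor=factor, lr_rate=hr_rate / factor,
                      hr_rate=hr_rate)


def degrade_batch(windows: Sequence[EEGWindow], task: SRTaskSpec):
    """Degrade every window; returns (X_lr, Y_hr, labels) arrays."""
    degrade = degrade_spatial if task.mode == "spatial" else degrade_temporal
    lr = [degrade(w, task) for w in windows]
    X, labels = stack_windows(lr)
    Y, _ = stack_windows(list(windows))
    return X, Y, labels


def _estimator_for(task: SRTaskSpec, montage: Montage, diffusion: bool,
                   cfg: TrainConfig, **model_kwargs):
    common = dict(mode=task.mode, factor=task.factor, montage=montage,
                  lr_channel_indices=task.lr_channel_indices,
                  epochs=cfg.epochs, batch_size=cfg.batch_size,
                  learning_rate=cfg.learning_rate,
                  weight_decay=cfg.weight_decay, patience=cfg.patience,
                  seed=cfg.seed, **model_kwargs)
    return DiffusionSuperResolver(**common) if diffusion else BiMambaRegressor(**common)


def train_model(train_windows: Sequence[EEGWindow],
                val_windows: Sequence[EEGWindow] | None,
                task: SRTaskSpec, montage: Montage,
                diffusion: bool = False, train_cfg: TrainConfig | None = None,
                **model_kwargs):
    """Train a regressor or diffusion model on degraded/clean window pairs.

    Returns the fitted estimator; its ``history_`` holds per-epoch train loss
    (and validation NMSE when a validation split is given — the
    best-validation parameters are restored at the end).
    """
    cfg = train_cfg or TrainConfig()
    X, Y, labels = degrade_batch(train_windows, task)
    val = None
    if val_windows:
        Xv, Yv, _ = degrade_batch(val_windows, task)
        val = (Xv, Yv)
    est = _estimator_for(task, montage, diffusion, cfg, **model_kwargs)
    est.fit(X, Y, labels=labels, validation_data=val)
    return est


def evaluate_model(estimator, test_windows: Sequence[EEGWindow],
                   task: SRTaskSpec, montage: Montage) -> dict:
    """Reconstruct every test window and aggregate the metric suite.

    Returns mean and standard deviation per metric plus derived MSE/RMSE.
    """
    X, Y, labels = degrade_batch(test_windows, task)
    pred = estimator.predict(X, labels=labels if estimator.cond_label else None)
    rate = test_windows[0].rate
    reports = [evaluate_pair(pred[i], Y[i], rate, montage)
               for i in range(len(test_windows))]
    out = {}
    for key in ("nmse", "pcc", "ssim", "psnr_db", "snr_db", "topo_smoothness",
                "imag_coherence"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        finite = [v for v in vals if np.isfinite(v)]
        if finite:
            out[f"{key}_mean"] = float(np.mean(finite))
            out[f"{key}_std"] = float(np.std(finite))
    mse = [float(((pred[i] - Y[i]) ** 2).mean()) for i in range(len(test_windows))]
    out["mse_mean"] = float(np.mean(mse))
    out["rmse_mean"] = float(np.mean(np.sqrt(mse)))
    band_keys = reports[0].bandpower_mae.keys()
    for b in band_keys:
        out[f"bandpower_mae_{b}"] = float(np.mean([r.bandpower_mae[b] for r in reports]))
    return out


def baseline_reconstructions(test_windows: Sequence[EEGWindow],
                             task: SRTaskSpec, montage: Montage) -> dict[str, np.ndarray]:
    """Non-learned reference reconstructions: naive upsampling (zero-padding /
    linear interpolation) and, for spatial tasks, the spherical-spline
    baseline."""
    degrade = degrade_spatial if task.mode == "spatial" else degrade_temporal
    lr = [degrade(w, task) for w in test_windows]
    X, _ = stack_windows(lr)
    out = {"naive": upsample_batch(X, task.mode, task.factor,
                                   lr_channel_indices=task.lr_channel_indices,
                                   hr_channels=len(montage))}
    if task.mode == "spatial":
        out["spline"] = np.stack([
            spline_upsample_baseline(w, task, montage) for w in lr])
    return out


def run_ablation(grid: AblationGrid,
                 train_windows: Sequence[EEGWindow],
                 val_windows: Sequence[EEGWindow] | None,
                 test_windows: Sequence[EEGWindow],
                 task: SRTaskSpec, montage: Montage,
                 train_cfg: TrainConfig | None = None,
                 baseline_kwargs: dict | None = None) -> pd.DataFrame:
    """Train and evaluate one model per grid value; returns a tidy table.

    ``presence`` sweeps the four (Mamba x Diffusion) on/off configurations
    (the Mamba-off variants swap the bottleneck for the convolutional
    stack); ``conditioning`` sweeps none / LR / LR+positions /
    LR+positions+label; ``sampling_init`` compares pure-noise and LR-biased
    one-step initialization.  Other axes vary a single backbone
    hyperparameter at baseline settings.
    """
    cfg = train_cfg or TrainConfig()
    base = dict(baseline_kwargs or {})
    rows = []
    for value in grid.values:
        kw = dict(base)
        diffusion = kw.pop("diffusion", False)
        if grid.axis == "presence":
            mamba_on, diffusion = value
            kw["bottleneck"] = "bimamba" if mamba_on else "conv"
        elif grid.axis == "conditioning":
            diffusion = True
            kw["cond_lr"] = value != "none"
            kw["cond_positions"] = "pos" in value
            kw["cond_label"] = "label" in value
        elif grid.axis == "sampling_init":
            diffusion = True
            kw["sampler_init"] = value
        else:
            kw[grid.axis] = value
        est = train_model(train_windows, val_windows, task, montage,
                          diffusion=diffusion, train_cfg=cfg, **kw)
        row = {"axis": grid.axis, "value": str(value),
               "n_params": est.n_params_}
        row.update(evaluate_model(est, test_windows, task, montage))
        rows.append(row)
    return pd.DataFrame(rows)
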
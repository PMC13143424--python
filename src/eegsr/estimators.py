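"""Scikit-learn-style estimators for EEG super-resolution.

Two estimators share one convolutional/state-space trunk:

* :class:`BiMambaRegressor` — deterministic regression from the naively
  upsampled low-resolution signal to the high-resolution signal (the
  "Mamba-only" model);
* :class:`DiffusionSuperResolver` — conditional denoising diffusion with
  the same trunk as denoiser and one-step sampling at inference (the full
  diffusion model).

Both follow the sklearn estimator contract: all hyperparameters are plain
``__init__`` arguments (so ``get_params``/``set_params``/``clone`` work),
``fit(X, y)`` learns from arrays shaped (n, C_lr, L_lr) -> (n, C_hr, L_hr),
fitted state lives in trailing-underscore attributes, and ``predict``
returns HR-shaped reconstructions.  ``score`` returns the negative NMSE so
that larger is better, as sklearn model selection expects.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from ._autodiff import no_grad, Tensor
from .denoiser import ConditioningBundle, ModelConfig, ReconstructionNet, NULL_LABEL
from .diffusion import (NoiseSchedule, SamplerSpec, make_schedule,
                        one_step_sample, multi_step_sample, training_step)
from .montage import Montage
from .nn import AdamW
from .ssm import BiMambaStackConfig, MambaBlockConfig

__all__ = ["BiMambaRegressor", "DiffusionSuperResolver", "upsample_batch"]


def upsample_batch(X_lr: np.ndarray, mode: str, factor: int,
                   lr_channel_indices=None, hr_channels: int | None = None) -> np.ndarray:
    """Vectorized naive LR -> HR-shaped lift for (n, C, L) arrays.

    Spatial: zero-padding at the HR ranks; temporal: per-channel linear
    interpolation with hold-last (output length = factor * L).
    """
    X_lr = np.asarray(X_lr, dtype=float)
    if mode == "spatial":
        n, _, L = X_lr.shape
        out = np.zeros((n, hr_channels, L))
        out[:, np.asarray(lr_channel_indices, dtype=int)] = X_lr
        return out
    n, C, L = X_lr.shape
    x_hr = np.arange(L * factor) / factor
    xp = np.arange(L, dtype=float)
    out = np.empty((n, C, L * factor))
    for i in range(n):
        for c in range(C):
            out[i, c] = np.interp(x_hr, xp, X_lr[i, c])
    return out


class _BaseSuperResolver(BaseEstimator, RegressorMixin):
    _diffusion = False

    def __init__(self, *, mode="spatial", factor=8, montage=None,
                 lr_channel_indices=None, base_width=64, depth=2,
                 bottleneck="bimamba", mamba_version=1, d_model=128, d_state=8,
                 n_heads=4, n_blocks=2, n_layers=2, cond_lr=True,
                 cond_positions=False, cond_label=False, n_classes=2,
                 dropout=0.1, emb_dim=32, epochs=30, batch_size=32,
                 learning_rate=1e-3, weight_decay=1e-4, patience=10, seed=0):
        self.mode = mode
        self.factor = factor
        self.montage = montage
        self.lr_channel_indices = lr_channel_indices
        self.base_width = base_width
        self.depth = depth
        self.bottleneck = bottleneck
        self.mamba_version = mamba_version
        self.d_model = d_model
        self.d_state = d_state
        self.n_heads = n_heads
        self.n_blocks = n_blocks
        self.n_layers = n_layers
        self.cond_lr = cond_lr
        self.cond_positions = cond_positions
        self.cond_label = cond_label
        self.n_classes = n_classes
        self.dropout = dropout
        self.emb_dim = emb_dim
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.patience = patience
        self.seed = seed

    # -- shared plumbing -------------------------------------------------

    def _model_config(self, hr_channels: int, hr_samples: int) -> ModelConfig:
        return ModelConfig(
            hr_channels=hr_channels, hr_samples=hr_samples,
            base_width=self.base_width, depth=self.depth,
            bottleneck=self.bottleneck,
            block=MambaBlockConfig(version=self.mamba_version,
                                   d_model=self.d_model, d_state=self.d_state,
                                   n_heads=self.n_heads),
            stack=BiMambaStackConfig(n_layers=self.n_layers,
                                     n_blocks_per_direction=self.n_blocks),
            cond_lr=self.cond_lr, cond_positions=self.cond_positions,
            cond_label=self.cond_label, n_classes=self.n_classes,
            dropout=self.dropout, emb_dim=self.emb_dim)

    def _upsample(self, X_lr: np.ndarray, hr_channels: int) -> np.ndarray:
        return upsample_batch(X_lr, self.mode, self.factor,
                              lr_channel_indices=self.lr_channel_indices,
                              hr_channels=hr_channels)

    def _cond_arrays(self):
        ranks = coords = None
        if self.cond_positions:
            if self.montage is None:
                raise ValueError("cond_positions requires a montage")
            ranks = np.asarray(self.montage.rank)
            coords = np.asarray(self.montage.positions)
        return ranks, coords

    def _validate_xy(self, X, y):
        X, y = np.asarray(X, float), np.asarray(y, float)
        if X.ndim != 3 or y.ndim != 3:
            raise ValueError("X and y must be (n, channels, samples) arrays")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y must have the same number of windows")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("inputs must be finite")
        if self.mode == "spatial":
            if self.lr_channel_indices is None:
                raise ValueError("spatial mode requires lr_channel_indices")
            if X.shape[2] != y.shape[2]:
                raise ValueError("spatial mode: LR and HR sample counts differ")
        else:
            if X.shape[2] * self.factor != y.shape[2]:
                raise ValueError("temporal mode: L_lr * factor != L_hr")
        return X, y

    def _labels_for(self, labels, n: int) -> np.ndarray | None:
        if not self.cond_label:
            return None
        if labels is None:
            return np.full(n, NULL_LABEL, dtype=int)
        return np.asarray(labels, dtype=int)

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: hyperparameters + named parameter tensors
        (+ the noise schedule for the diffusion estimator)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("cannot save an unfitted estimator")
        meta = {"params": {k: v for k, v in self.get_params().items()
                           if k not in ("montage", "lr_channel_indices")},
                "class": type(self).__name__,
                "hr_channels": self.hr_channels_, "hr_samples": self.hr_samples_}
        if self.lr_channel_indices is not None:
            meta["lr_channel_indices"] = np.asarray(self.lr_channel_indices).tolist()
        if getattr(self, "schedule_", None) is not None:
            meta["schedule"] = self.schedule_.to_dict()
        arrays = {f"param::{k}": v for k, v in self.net_.state_dict().items()}
        if self.montage is not None:
            arrays["montage_positions"] = self.montage.positions
            meta["montage_names"] = list(self.montage.names)
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "_BaseSuperResolver":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
        params = meta["params"]
        if "montage_names" in meta:
            params["montage"] = Montage(names=tuple(meta["montage_names"]),
                                        positions=arrays.pop("montage_positions"))
        if "lr_channel_indices" in meta:
            params["lr_channel_indices"] = np.asarray(meta["lr_channel_indices"], dtype=int)
        est = cls(**params)
        est.hr_channels_ = meta["hr_channels"]
        est.hr_samples_ = meta["hr_samples"]
        rng = np.random.default_rng(est.seed)
        if meta.get("schedule"):
            est.schedule_ = NoiseSchedule.from_dict(meta["schedule"])
            est.net_ = ReconstructionNet(
                est._model_config(est.hr_channels_, est.hr_samples_), rng,
                diffusion=True, max_t=est.schedule_.T)
        else:
            est.net_ = ReconstructionNet(
                est._model_config(est.hr_channels_, est.hr_samples_), rng,
                diffusion=False)
        est.net_.load_state_dict(
            {k[len("param::"):]: v for k, v in arrays.items() if k.startswith("param::")})
        est.history_ = []
        return est

    def score(self, X, y, **kwargs) -> float:
        """Negative NMSE of the reconstruction (larger is better)."""
        pred = self.predict(X)
        y = np.asarray(y, float)
        return -float(((pred - y) ** 2).sum() / (y ** 2).sum())


class BiMambaRegressor(_BaseSuperResolver):
    """Deterministic super-resolution regressor with a bidirectional Mamba
    bottleneck (set ``bottleneck='conv'`` for the pure encoder–decoder
    baseline).  Minimizes MSE between the reconstruction and the HR target.
    """

    def fit(self, X, y, labels=None, validation_data=None):
        X, y = self._validate_xy(X, y)
        n, (C_hr, L_hr) = X.shape[0], y.shape[1:]
        rng = np.random.default_rng(self.seed)
        cfg = self._model_config(C_hr, L_hr)
        self.net_ = ReconstructionNet(cfg, rng, diffusion=False)
        self.hr_channels_, self.hr_samples_ = C_hr, L_hr
        self.schedule_ = None
        lr_up = self._upsample(X, C_hr)
        ranks, coords = self._cond_arrays()
        labels_arr = self._labels_for(labels, n)
        n_batches = max(1, n // self.batch_size)
        opt = AdamW(self.net_.parameters(), lr=self.learning_rate,
                    weight_decay=self.weight_decay,
                    total_steps=self.epochs * n_batches)
        self.history_ = []
        # pre-training loss of the untrained network, for convergence checks
        with no_grad():
            pred0 = self.net_(lr_up, ConditioningBundle(
                ranks=ranks, coords=coords, label=labels_arr))
        self.history_.append({"epoch": -1,
                              "train_loss": float(((pred0.data - y) ** 2).mean())})
        best = (np.inf, None, -1)
        shuffle_rng = np.random.default_rng([self.seed, 1])
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            self.net_.train()
            for b in range(n_batches):
                idx = order[b * self.batch_size:(b + 1) * self.batch_size]
                if len(idx) == 0:
                    continue
                cond = ConditioningBundle(
                    ranks=ranks, coords=coords,
                    label=None if labels_arr is None else labels_arr[idx])
                pred = self.net_(lr_up[idx], cond)
                diff = pred - Tensor(y[idx])
                loss = (diff * diff).mean()
                if not np.isfinite(loss.data):
                    break  # divergence: keep the last good parameters
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses)) if losses else np.nan}
            if validation_data is not None:
                Xv, yv = validation_data[:2]
                pv = self.predict(Xv)
                yv = np.asarray(yv, float)
                entry["val_nmse"] = float(((pv - yv) ** 2).sum() / (yv ** 2).sum())
                if entry["val_nmse"] < best[0]:
                    best = (entry["val_nmse"], self.net_.state_dict(), epoch)
                elif epoch - best[2] >= self.patience:
                    self.history_.append(entry)
                    break
            self.history_.append(entry)
        if best[1] is not None:
            self.net_.load_state_dict(best[1])
        self.net_.eval()
        self.n_params_ = self.net_.n_parameters()
        return self

    def predict(self, X, labels=None):
        X = np.asarray(X, float)
        lr_up = self._upsample(X, self.hr_channels_)
        ranks, coords = self._cond_arrays()
        labels_arr = self._labels_for(labels, X.shape[0])
        self.net_.eval()
        with no_grad():
            out = self.net_(lr_up, ConditioningBundle(ranks=ranks, coords=coords,
                                                      label=labels_arr))
        return out.data


class DiffusionSuperResolver(_BaseSuperResolver):
    """Conditional diffusion super-resolver with one-step sampling.

    Training adds schedule noise to the HR target at uniform timesteps and
    regresses the denoiser output onto the clean signal (prediction type
    "sample" by default) or the noise ("epsilon").  Inference initializes at
    the maximum timestep from noise optionally biased by the upsampled LR
    signal and calls the denoiser exactly once (``sampler_mode='one_step'``),
    or runs the reference DDPM/DDIM recursions.
    """

    _diffusion = True

    def __init__(self, *, mode="spatial", factor=8, montage=None,
                 lr_channel_indices=None, base_width=64, depth=2,
                 bottleneck="bimamba", mamba_version=1, d_model=128, d_state=8,
                 n_heads=4, n_blocks=2, n_layers=2, cond_lr=True,
                 cond_positions=False, cond_label=False, n_classes=2,
                 dropout=0.1, emb_dim=32, epochs=50, batch_size=32,
                 learning_rate=1e-3, weight_decay=1e-4, patience=10, seed=0,
                 timesteps=1000, beta_min=1e-4, beta_max=0.015,
                 prediction_type="sample", sampler_mode="one_step",
                 sampler_steps=50, sampler_init="noise_plus_upsampled_lr",
                 init_noise_scale=1.0, bias_high_t=False):
        super().__init__(
            mode=mode, factor=factor, montage=montage,
            lr_channel_indices=lr_channel_indices, base_width=base_width,
            depth=depth, bottleneck=bottleneck, mamba_version=mamba_version,
            d_model=d_model, d_state=d_state, n_heads=n_heads,
            n_blocks=n_blocks, n_layers=n_layers, cond_lr=cond_lr,
            cond_positions=cond_positions, cond_label=cond_label,
            n_classes=n_classes, dropout=dropout, emb_dim=emb_dim,
            epochs=epochs, batch_size=batch_size, learning_rate=learning_rate,
            weight_decay=weight_decay, patience=patience, seed=seed)
        self.timesteps = timesteps
        self.beta_min = beta_min
        self.beta_max = beta_max
        self.prediction_type = prediction_type
        self.sampler_mode = sampler_mode
        self.sampler_steps = sampler_steps
        self.sampler_init = sampler_init
        self.init_noise_scale = init_noise_scale
        self.bias_high_t = bias_high_t

    def fit(self, X, y, labels=None, validation_data=None):
        X, y = self._validate_xy(X, y)
        n, (C_hr, L_hr) = X.shape[0], y.shape[1:]
        rng = np.random.default_rng(self.seed)
        self.schedule_ = make_schedule(self.timesteps, self.beta_min,
                                       self.beta_max, self.prediction_type)
        cfg = self._model_config(C_hr, L_hr)
        self.net_ = ReconstructionNet(cfg, rng, diffusion=True,
                                      max_t=self.schedule_.T)
        self.hr_channels_, self.hr_samples_ = C_hr, L_hr
        lr_up = self._upsample(X, C_hr)
        ranks, coords = self._cond_arrays()
        labels_arr = self._labels_for(labels, n)
        n_batches = max(1, n // self.batch_size)
        opt = AdamW(self.net_.parameters(), lr=self.learning_rate,
                    weight_decay=self.weight_decay,
                    total_steps=self.epochs * n_batches)
        self.history_ = []
        best = (np.inf, None, -1)
        shuffle_rng = np.random.default_rng([self.seed, 1])
        step_rng = np.random.default_rng([self.seed, 2])
        for epoch in range(self.epochs):
            order = shuffle_rng.permutation(n)
            losses = []
            self.net_.train()
            for b in range(n_batches):
                idx = order[b * self.batch_size:(b + 1) * self.batch_size]
                if len(idx) == 0:
                    continue
                batch = {"hr": y[idx], "lr_up": lr_up[idx] if self.cond_lr else None,
                         "ranks": ranks, "coords": coords,
                         "label": None if labels_arr is None else labels_arr[idx]}
                try:
                    loss = training_step(batch, self.net_, self.schedule_,
                                         step_rng, bias_high_t=self.bias_high_t)
                except FloatingPointError:
                    break  # divergence: keep the last good parameters
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            entry = {"epoch": epoch, "train_loss": float(np.mean(losses)) if losses else np.nan}
            if validation_data is not None:
                Xv, yv = validation_data[:2]
                pv = self.predict(Xv)
                yv = np.asarray(yv, float)
                entry["val_nmse"] = float(((pv - yv) ** 2).sum() / (yv ** 2).sum())
                if entry["val_nmse"] < best[0]:
                    best = (entry["val_nmse"], self.net_.state_dict(), epoch)
                elif epoch - best[2] >= self.patience:
                    self.history_.append(entry)
                    break
            self.history_.append(entry)
        if best[1] is not None:
            self.net_.load_state_dict(best[1])
        self.net_.eval()
        self.n_params_ = self.net_.n_parameters()
        return self

    def _denoise_fn(self):
        def fn(x_t, cond, t):
            with no_grad():
                cond = ConditioningBundle(lr_up=cond.lr_up, ranks=cond.ranks,
                                          coords=cond.coords, label=cond.label,
                                          timestep=t)
                return self.net_(x_t, cond).data
        return fn

    def predict(self, X, labels=None, sampler: SamplerSpec | None = None,
                rng: np.random.Generator | None = None):
        X = np.asarray(X, float)
        lr_up = self._upsample(X, self.hr_channels_)
        ranks, coords = self._cond_arrays()
        labels_arr = self._labels_for(labels, X.shape[0])
        cond = ConditioningBundle(lr_up=lr_up if self.cond_lr else None,
                                  ranks=ranks, coords=coords, label=labels_arr)
        spec = sampler or SamplerSpec(mode=self.sampler_mode,
                                      n_steps=self.sampler_steps,
                                      init=self.sampler_init,
                                      init_noise_scale=self.init_noise_scale)
        rng = rng or np.random.default_rng([self.seed, 3])
        self.net_.eval()
        if spec.mode == "one_step":
            return one_step_sample(lr_up, cond, self._denoise_fn(),
                                   self.schedule_, spec, rng)
        return multi_step_sample(lr_up, cond, self._denoise_fn(),
                                 self.schedule_, spec, rng)
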
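"""Recording-level cleaning, normalization, windowing and degradation.

The pipeline mirrors standard EEG practice: bad-channel detection by
variance/flatness thresholds, trial rejection above a 30% bad-channel
fraction, spherical-spline repair of surviving bad channels, 50 Hz notch +
zero-phase FIR bandpass, per-channel z-scoring, 2-s windowing with a seeded
80/10/10 split.  The same module provides the HR->LR degradation operators
(channel masking, decimation) and the LR->HR-shaped naive upsamplers
(zero-padding, linear interpolation, spherical-spline baseline) that define
the super-resolution tasks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import signal as sps

from .montage import Montage
from .windows import EEGWindow, SRTaskSpec

__all__ = [
    "FilterSpec", "SplitSpec", "Recording",
    "detect_bad_channels", "reject_or_repair", "spherical_spline_reconstruct",
    "apply_filters", "zscore", "segment_and_split",
    "degrade_spatial", "degrade_temporal", "upsample_to_hr_shape",
    "spline_upsample_baseline", "read_recording",
]

FLATLINE_VAR_THRESHOLD = 1e-10
SATURATION_DIFF_THRESHOLD = 1e-8
REJECTION_FRACTION = 0.30


@dataclass
class Recording:
    """A continuous multichannel recording prior to windowing."""

    data: np.ndarray  # (C, S)
    rate: float
    montage: Montage
    label: int = 0


@dataclass(frozen=True)
class FilterSpec:
    """Notch + FIR bandpass configuration (e.g. 50 Hz notch, 0.5-40 Hz band)."""

    notch_hz: float | None = 50.0
    band_lo: float = 0.5
    band_hi: float = 40.0
    fir_order: int | None = None  # None: 3 * rate / band_lo, rounded odd
    window_fn: str = "hamming"

    def validate(self, rate: float) -> None:
        if not (0 < self.band_lo < self.band_hi < rate / 2):
            raise ValueError(
                f"passband ({self.band_lo}-{self.band_hi} Hz) infeasible for "
                f"rate {rate} Hz")
        if self.notch_hz is not None and not (0 < self.notch_hz < rate / 2):
            raise ValueError(f"notch at {self.notch_hz} Hz above Nyquist")


@dataclass(frozen=True)
class SplitSpec:
    """Fractional train/val/test split with a shuffling seed."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def detect_bad_channels(window: EEGWindow) -> np.ndarray:
    """Flag each channel as ``good`` / ``flatline`` / ``saturation``.

    Flatline: channel variance below 1e-10 with the signal itself at
    (numerically) zero level — a dead channel.  Saturation: largest absolute
    consecutive difference below 1e-8 while the channel sits at a non-zero
    level — an amplifier stuck at a rail.
    """
    x = window.data
    var = x.var(axis=1)
    max_diff = np.abs(np.diff(x, axis=1)).max(axis=1) if x.shape[1] > 1 else var * 0
    level = np.abs(x).max(axis=1)
    flags = np.full(x.shape[0], "good", dtype=object)
    saturated = (max_diff < SATURATION_DIFF_THRESHOLD) & (level > np.sqrt(FLATLINE_VAR_THRESHOLD))
    flags[saturated] = "saturation"
    flags[(var < FLATLINE_VAR_THRESHOLD) & ~saturated] = "flatline"
    return flags


def _legendre_gain_coeffs(m: int, n_terms: int) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n ** m * (n + 1) ** m) / (4 * np.pi)
    return coeffs


def spherical_spline_reconstruct(window_data: np.ndarray, good_indices,
                                 target_indices, montage: Montage,
                                 m: int = 4, lam: float = 1e-5,
                                 n_terms: int = 50) -> np.ndarray:
    """Spherical-spline interpolation of scalp potentials (Perrin-style).

    Solves, per time sample, the bordered system with kernel
    ``g(cos theta) = sum_n (2n+1) / (n (n+1))**m * P_n(cos theta) / (4 pi)``
    over the good electrodes (ridge ``lam`` on the diagonal, constant term
    enforced) and evaluates the fitted field at the target electrodes.

    ``window_data`` is channels x samples; returns ``len(target_indices)`` x
    samples.
    """
    good = np.asarray(good_indices, dtype=int)
    targets = np.asarray(target_indices, dtype=int)
    if len(good) < 4:
        raise ValueError("spherical splines need at least 4 good electrodes")
    pos = montage.positions
    coeffs = _legendre_gain_coeffs(m, n_terms)

    cos_gg = np.clip(pos[good] @ pos[good].T, -1.0, 1.0)
    cos_tg = np.clip(pos[targets] @ pos[good].T, -1.0, 1.0)
    G = legendre.legval(cos_gg, coeffs)
    Gt = legendre.legval(cos_tg, coeffs)

    k = len(good)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = G + lam * np.eye(k)
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    rhs = np.zeros((k + 1, window_data.shape[1]))
    rhs[:k] = window_data[good]
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "spherical-spline system is singular; increase the regularizer "
            "lam") from err
    c, const = sol[:k], sol[k]
    return Gt @ c + const[None, :]


def reject_or_repair(window: EEGWindow, flags: np.ndarray,
                     montage: Montage | None = None) -> EEGWindow | None:
    """Reject the trial above a 30% bad-channel fraction, else spline-repair.

    Returns ``None`` as the rejection marker.
    """
    montage = montage or window.montage
    bad = np.flatnonzero(np.asarray(flags, dtype=object) != "good")
    frac = len(bad) / len(flags)
    if frac > REJECTION_FRACTION or len(bad) == len(flags):
        return None
    if len(bad) == 0:
        return window
    good = np.flatnonzero(np.asarray(flags, dtype=object) == "good")
    repaired = window.data.copy()
    repaired[bad] = spherical_spline_reconstruct(window.data, good, bad, montage)
    return window.with_data(repaired)


def _fir_taps(spec: FilterSpec, rate: float, n_samples: int) -> int:
    taps = spec.fir_order or int(round(3 * rate / spec.band_lo))
    taps |= 1  # odd
    # zero-phase filtering needs the signal to cover the filter's edges
    max_taps = (n_samples - 2) // 3
    if max_taps < 11:
        raise ValueError(
            f"recording too short ({n_samples} samples) for FIR band "
            f"{spec.band_lo}-{spec.band_hi} Hz at {rate} Hz")
    return min(taps, max_taps | 1)


def apply_filters(data: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase notch + FIR bandpass over the time axis of ``(C, S)`` data."""
    spec.validate(rate)
    out = np.asarray(data, dtype=float)
    if spec.notch_hz is not None:
        b, a = sps.iirnotch(spec.notch_hz, Q=30.0, fs=rate)
        out = sps.filtfilt(b, a, out, axis=-1)
    taps = _fir_taps(spec, rate, out.shape[-1])
    h = sps.firwin(taps, [spec.band_lo, spec.band_hi], pass_zero=False,
                   window=spec.window_fn, fs=rate)
    return sps.filtfilt(h, [1.0], out, axis=-1)


def zscore(window: EEGWindow, common_average: bool = False) -> EEGWindow:
    """Per-channel z-scoring ``(x - mu_c) / (sigma_c + 1e-8)``.

    Population sigma; the 1e-8 stabilizer maps constant channels to zero.
    Optionally applies a common average reference first.
    """
    x = window.data
    if common_average:
        x = x - x.mean(axis=0, keepdims=True)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return window.with_data((x - mu) / (sd + 1e-8))


def segment_and_split(recording: Recording, duration: float = 2.0,
                      split: SplitSpec = SplitSpec()) -> tuple[list[EEGWindow], list[EEGWindow], list[EEGWindow]]:
    """Cut non-overlapping windows then shuffle and split by fractions."""
    split.validate()
    n = round(recording.rate * duration)
    n_windows = recording.data.shape[1] // n
    if n_windows < 3:
        raise ValueError(
            f"recording yields only {n_windows} windows of {duration} s; "
            "need at least 3 to split")
    windows = [
        EEGWindow(data=recording.data[:, i * n:(i + 1) * n], rate=recording.rate,
                  duration=duration, label=recording.label,
                  montage=recording.montage)
        for i in range(n_windows)
    ]
    rng = np.random.default_rng(split.seed)
    order = rng.permutation(n_windows)
    n_train = int(round(split.train * n_windows))
    n_val = int(round(split.val * n_windows))
    idx_train = order[:n_train]
    idx_val = order[n_train:n_train + n_val]
    idx_test = order[n_train + n_val:]
    return ([windows[i] for i in idx_train], [windows[i] for i in idx_val],
            [windows[i] for i in idx_test])


def degrade_spatial(hr: EEGWindow, task: SRTaskSpec) -> EEGWindow:
    """Case-1-style channel masking: keep the task's LR electrode rows."""
    if task.mode != "spatial":
        raise ValueError("degrade_spatial requires a spatial task")
    idx = task.lr_channel_indices
    if idx.max(initial=-1) >= hr.n_channels or idx.min(initial=0) < 0:
        raise IndexError("lr_channel_indices out of range for this window")
    return hr.with_data(hr.data[idx], montage=hr.montage.subset(idx))


def degrade_temporal(hr: EEGWindow, task: SRTaskSpec) -> EEGWindow:
    """Decimation: keep every ``factor``-th sample starting at index 0.

    Anti-aliasing is assumed to come from the pipeline's prior bandpass;
    when the signal may exceed the LR Nyquist, low-pass first.
    """
    if task.mode != "temporal":
        raise ValueError("degrade_temporal requires a temporal task")
    if hr.n_samples % task.factor != 0:
        raise ValueError(
            f"factor {task.factor} does not divide {hr.n_samples} samples")
    return hr.with_data(hr.data[:, ::task.factor], rate=hr.rate / task.factor)


def upsample_to_hr_shape(lr: EEGWindow, task: SRTaskSpec,
                         montage: Montage | None = None) -> np.ndarray:
    """Naive LR -> HR-shaped lift used as conditioning and sampler init.

    Spatial: LR rows placed at their HR montage ranks, all other rows zero.
    Temporal: per-channel linear interpolation onto the HR grid, holding the
    last LR sample beyond its position (output length = factor * LR length).
    """
    if task.mode == "spatial":
        if montage is None:
            raise ValueError("spatial upsampling needs the HR montage")
        C_hr = len(montage)
        out = np.zeros((C_hr, lr.n_samples))
        out[task.lr_channel_indices] = lr.data
        return out
    factor = task.factor
    L = lr.n_samples
    x_hr = np.arange(L * factor) / factor
    xp = np.arange(L, dtype=float)
    return np.stack([np.interp(x_hr, xp, row) for row in lr.data])


def spline_upsample_baseline(lr: EEGWindow, task: SRTaskSpec, montage: Montage,
                             m: int = 4, lam: float = 1e-5,
                             n_terms: int = 50) -> np.ndarray:
    """Classical spherical-spline interpolation baseline (spatial mode).

    Observed LR channels are copied through unchanged; the missing HR
    channels are filled by the spline fitted per time sample.
    """
    if task.mode != "spatial":
        raise ValueError("the spline baseline applies to spatial tasks")
    C_hr = len(montage)
    lr_idx = task.lr_channel_indices
    missing = np.setdiff1d(np.arange(C_hr), lr_idx)
    out = np.zeros((C_hr, lr.n_samples))
    out[lr_idx] = lr.data
    hr_shaped = np.zeros((C_hr, lr.n_samples))
    hr_shaped[lr_idx] = lr.data
    out[missing] = spherical_spline_reconstruct(
        hr_shaped, lr_idx, missing, montage, m=m, lam=lam, n_terms=n_terms)
    return out


def read_recording(path, montage: Montage, label: int = 0) -> Recording:
    """Read an EDF or FIF recording, matching channels to ``montage`` by name.

    Channel labels are compared case-insensitively; every montage electrode
    must be present in the file.
    """
    import mne

    path = str(path)
    if path.lower().endswith(".edf"):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.lower().endswith(".fif"):
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path}")
    lookup = {name.strip().strip(".").lower(): i
              for i, name in enumerate(raw.ch_names)}
    rows = []
    for name in montage.names:
        key = name.lower()
        if key not in lookup:
            raise KeyError(f"electrode {name!r} not found in {path}")
        rows.append(lookup[key])
    data = raw.get_data()[rows]
    return Recording(data=data, rate=float(raw.info["sfreq"]),
                     montage=montage, label=label)
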
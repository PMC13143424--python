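"""Core data containers: fixed-length EEG windows and super-resolution tasks."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .montage import Montage

__all__ = ["EEGWindow", "SRTaskSpec", "save_windows", "load_windows", "stack_windows"]


@dataclass
class EEGWindow:
    """One fixed-duration multichannel segment (z-scored units).

    ``data`` is channels x samples; ``samples`` must equal
    ``round(rate * duration)`` and ``channels`` must match the montage.
    """

    data: np.ndarray
    rate: float
    duration: float
    label: int
    montage: Montage

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("window data must be channels x samples")
        C, S = self.data.shape
        if S != round(self.rate * self.duration):
            raise ValueError(
                f"samples ({S}) != round(rate*duration) "
                f"({round(self.rate * self.duration)})")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("window data must be finite")
        if C != len(self.montage):
            raise ValueError(f"channels ({C}) != montage size ({len(self.montage)})")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def with_data(self, data, rate: float | None = None,
                  montage: Montage | None = None) -> "EEGWindow":
        rate = self.rate if rate is None else rate
        montage = self.montage if montage is None else montage
        return EEGWindow(data=np.asarray(data, dtype=float), rate=rate,
                         duration=self.duration, label=self.label, montage=montage)


@dataclass(frozen=True)
class SRTaskSpec:
    """Super-resolution task: spatial channel upsampling or temporal rate upsampling."""

    mode: str  # "spatial" | "temporal"
    factor: int
    lr_channel_indices: np.ndarray | None = None  # spatial mode
    lr_rate: float | None = None  # temporal mode
    hr_channels: int | None = None
    hr_rate: float | None = None

    def __post_init__(self):
        if self.mode not in ("spatial", "temporal"):
            raise ValueError(f"unknown task mode {self.mode!r}")
        if self.factor not in (1, 2, 4, 8):
            raise ValueError("factor must be one of 1, 2, 4, 8")
        if self.mode == "spatial":
            if self.lr_channel_indices is None:
                raise ValueError("spatial task needs lr_channel_indices")
            idx = np.asarray(self.lr_channel_indices, dtype=int)
            object.__setattr__(self, "lr_channel_indices", idx)
            if self.hr_channels is not None and len(idx) * self.factor != self.hr_channels:
                raise ValueError(
                    f"|lr_channel_indices| ({len(idx)}) x factor ({self.factor}) "
                    f"!= hr channels ({self.hr_channels})")
        else:
            if self.lr_rate is None:
                raise ValueError("temporal task needs lr_rate")
            if self.hr_rate is not None and abs(self.lr_rate * self.factor - self.hr_rate) > 1e-9:
                raise ValueError(
                    f"lr_rate ({self.lr_rate}) x factor ({self.factor}) != "
                    f"hr rate ({self.hr_rate})")


def stack_windows(windows: Sequence[EEGWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack windows into (n, C, S) data and (n,) label arrays."""
    data = np.stack([w.data for w in windows])
    labels = np.array([w.label for w in windows], dtype=int)
    return data, labels


def save_windows(path, windows: Sequence[EEGWindow]) -> None:
    """Persist a homogeneous window list to an HDF5 container."""
    import h5py

    if not windows:
        raise ValueError("cannot save an empty window list")
    w0 = windows[0]
    data, labels = stack_windows(windows)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=data)
        fh.create_dataset("labels", data=labels)
        fh.attrs["rate"] = w0.rate
        fh.attrs["duration"] = w0.duration
        fh.create_dataset("montage_names",
                          data=np.array(w0.montage.names, dtype="S16"))
        fh.create_dataset("montage_positions", data=w0.montage.positions)


def load_windows(path) -> list[EEGWindow]:
    import h5py

    with h5py.File(path, "r") as fh:
        data = fh["data"][...]
        labels = fh["labels"][...]
        rate = float(fh.attrs["rate"])
        duration = float(fh.attrs["duration"])
        names = tuple(n.decode() for n in fh["montage_names"][...])
        pos = fh["montage_positions"][...]
    montage = Montage(names=names, positions=pos)
    return [EEGWindow(data=d, rate=rate, duration=duration, label=int(l), montage=montage)
            for d, l in zip(data, labels)]
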
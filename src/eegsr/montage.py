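"""Electrode montages on the unit sphere.

A :class:`Montage` holds named scalp electrodes with 3-D head-frame positions
projected onto the unit sphere (x right, y front, z up).  Spherical-spline
interpolation, the synthetic leadfield and the topographic metrics only need
this angular geometry, so no realistic head model is attempted.

Realized 10-10 coordinates come from MNE's ``standard_1005`` template; the
canonical channel sets for 64 (BCI2000 motor-imagery cap), 62 (SEED-style cap,
with PO9/PO10 standing in for the cerebellar leads absent from the 10-05
template) and nested 32/16/8 low-density subsets are built in.  Any other
channel count falls back to a synthetic Fibonacci grid on the upper
hemisphere unless that fallback is disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

__all__ = [
    "Montage", "build_standard_montage", "select_lr_subset",
    "great_circle_distance", "STANDARD_CHANNEL_SETS",
]

_NAMES_64 = [
    "Fc5", "Fc3", "Fc1", "Fcz", "Fc2", "Fc4", "Fc6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "Cp5", "Cp3", "Cp1", "Cpz", "Cp2", "Cp4", "Cp6",
    "Fp1", "Fpz", "Fp2",
    "Af7", "Af3", "Afz", "Af4", "Af8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "Ft7", "Ft8", "T7", "T8", "T9", "T10", "Tp7", "Tp8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "Po7", "Po3", "Poz", "Po4", "Po8",
    "O1", "Oz", "O2", "Iz",
]

_NAMES_62 = [
    "Fp1", "Fpz", "Fp2", "Af3", "Af4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "Ft7", "Fc5", "Fc3", "Fc1", "Fcz", "Fc2", "Fc4", "Fc6", "Ft8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "Tp7", "Cp5", "Cp3", "Cp1", "Cpz", "Cp2", "Cp4", "Cp6", "Tp8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "Po7", "Po5", "Po3", "Poz", "Po4", "Po6", "Po8",
    "Po9", "O1", "Oz", "O2", "Po10",
]

_NAMES_32 = [
    "Fp1", "Fp2", "Afz", "F7", "F3", "Fz", "F4", "F8",
    "Fc5", "Fc1", "Fc2", "Fc6", "T7", "C3", "Cz", "C4", "T8",
    "Cp5", "Cp1", "Cp2", "Cp6", "P7", "P3", "Pz", "P4", "P8",
    "Po3", "Poz", "Po4", "O1", "Oz", "O2",
]

_NAMES_16 = [
    "Fp1", "Fp2", "F7", "F3", "F4", "F8", "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "P4", "P8", "Oz",
]

_NAMES_8 = ["Fp1", "Fp2", "C3", "C4", "T7", "T8", "O1", "O2"]

STANDARD_CHANNEL_SETS: dict[int, list[str]] = {
    8: _NAMES_8, 16: _NAMES_16, 32: _NAMES_32, 62: _NAMES_62, 64: _NAMES_64,
}


@dataclass(frozen=True)
class Montage:
    """Named electrodes with unit-sphere positions and canonical ranks."""

    names: tuple[str, ...]
    positions: np.ndarray  # (C, 3), unit norm
    rank: np.ndarray = field(default=None)  # permutation of 0..C-1

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        rank = (np.arange(len(self.names)) if self.rank is None
                else np.asarray(self.rank, dtype=int))
        object.__setattr__(self, "rank", rank)
        self.validate()

    def validate(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("montage electrode names must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("montage positions must be finite")
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("montage positions must lie on the unit sphere")
        if sorted(self.rank.tolist()) != list(range(len(self.names))):
            raise ValueError("rank must be a permutation of 0..C-1")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def subset(self, indices) -> "Montage":
        """Montage restricted to ``indices`` (rank renumbered to 0..k-1)."""
        indices = np.asarray(indices, dtype=int)
        return Montage(
            names=tuple(self.names[i] for i in indices),
            positions=self.positions[indices],
            rank=np.arange(len(indices)),
        )

    def index_of(self, name: str) -> int:
        lowered = [n.lower() for n in self.names]
        return lowered.index(name.lower())

    # -- plain-text IO (name x y z per line) -----------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, p in zip(self.names, self.positions):
                fh.write(f"{name} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")

    @classmethod
    def from_file(cls, path) -> "Montage":
        names, pos = [], []
        for line in Path(path).read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            names.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
        pos = np.asarray(pos)
        pos /= np.linalg.norm(pos, axis=1, keepdims=True)
        return cls(names=tuple(names), positions=pos)


@lru_cache(maxsize=1)
def _template_positions() -> dict[str, np.ndarray]:
    """Unit-sphere positions for every 10-05 electrode (lower-cased keys)."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ch_pos = mne.channels.make_standard_montage("standard_1005").get_positions()["ch_pos"]
    pts = np.array(list(ch_pos.values()))
    # least-squares sphere fit: |p|^2 = 2 p.c + (r^2 - |c|^2)
    A = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    out = {}
    for name, p in ch_pos.items():
        v = np.asarray(p) - center
        out[name.lower()] = v / np.linalg.norm(v)
    return out


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform grid on the upper hemisphere (z >= 0)."""
    i = np.arange(n)
    z = 1.0 - i / max(n, 1) * 0.95  # keep away from the equatorial rim
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1 - z ** 2, 0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def build_standard_montage(n_channels: int, synthetic_fallback: bool = True) -> Montage:
    """Build the canonical montage for ``n_channels`` electrodes.

    Known counts (8, 16, 32, 62, 64) use realized 10-10 positions; other
    counts use a synthetic spherical grid named ``E0..E{n-1}`` unless
    ``synthetic_fallback`` is False, in which case a ``ValueError`` is raised.
    """
    if n_channels in STANDARD_CHANNEL_SETS:
        names = STANDARD_CHANNEL_SETS[n_channels]
        table = _template_positions()
        pos = np.array([table[n.lower()] for n in names])
        return Montage(names=tuple(names), positions=pos)
    if not synthetic_fallback:
        raise ValueError(
            f"no standard montage for {n_channels} channels and the synthetic "
            "grid fallback is disabled; known counts are "
            f"{sorted(STANDARD_CHANNEL_SETS)}")
    return Montage(
        names=tuple(f"E{i}" for i in range(n_channels)),
        positions=_fibonacci_hemisphere(n_channels),
    )


def great_circle_distance(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle (radians) between unit vectors; broadcasts over leading axes."""
    cross = np.linalg.norm(np.cross(u, v), axis=-1)
    dot = np.sum(u * v, axis=-1)
    return np.arctan2(cross, dot)


def select_lr_subset(montage: Montage, factor: int) -> np.ndarray:
    """Deterministic low-density channel subset for spatial degradation.

    Greedy farthest-point sampling on the sphere, seeded by the vertex
    electrode (closest to +z, ties broken by rank), maximizing spatial
    coverage of the retained electrodes.  Returns rank-ordered indices.
    """
    C = len(montage)
    if factor == 1:
        return np.argsort(montage.rank)
    if C % factor != 0:
        raise ValueError(
            f"factor {factor} does not divide the {C}-channel montage; the "
            f"achievable subset size would be {C // factor}")
    n_sel = C // factor
    order = np.argsort(montage.rank)  # iterate in canonical rank order for ties
    pos = montage.positions
    z = pos[order, 2]
    seed = order[int(np.argmax(z))]  # first max in rank order
    selected = [seed]
    min_dist = great_circle_distance(pos, pos[seed])
    while len(selected) < n_sel:
        # argmax over rank order breaks ties toward the lower rank
        cand = order[int(np.argmax(min_dist[order]))]
        selected.append(cand)
        min_dist = np.minimum(min_dist, great_circle_distance(pos, pos[cand]))
    return np.array(sorted(selected, key=lambda i: montage.rank[i]), dtype=int)
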
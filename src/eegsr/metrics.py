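"""Reconstruction-fidelity metric suite for multichannel EEG.

Point-wise accuracy (NMSE, PSNR, SNR), linear similarity (per-channel
Pearson correlation averaged over the montage), structural similarity (a
1-D sliding-window SSIM per channel), spatial plausibility (topographic
Laplacian smoothness on the electrode graph), spectral preservation
(per-band log-power MAE from Welch periodograms), connectivity structure
(imaginary coherence, insensitive to zero-lag volume conduction) and a
Fréchet distance between Gaussian feature embeddings of window sets.

Conventions fixed for determinism: Welch with Hann windows of
``min(L, 256)`` samples and 50% overlap; SSIM with a length-11 Gaussian
window (sigma 1.5) and the canonical K1=0.01 / K2=0.03 constants on the
reference signal's dynamic range; PSNR with MAX=1 for z-scored signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

from .montage import Montage, great_circle_distance
from .synthetic import BANDS

__all__ = [
    "MetricReport", "BandDefinition", "nmse", "pcc", "ssim", "psnr", "snr",
    "topo_smoothness", "bandpower_mae", "imag_coherence", "frechet_distance",
    "eeg_fid", "RandomConvFeatureExtractor", "evaluate_pair",
]

PSNR_INF_SENTINEL = float("inf")


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo: float
    hi: float


@dataclass
class MetricReport:
    """Flat container for the full metric suite; JSON-serializable."""

    nmse: float
    pcc: float
    ssim: float
    psnr_db: float
    snr_db: float
    topo_smoothness: float | None = None
    bandpower_mae: dict | None = None
    imag_coherence: float | None = None
    fid: float | None = None
    meta: dict | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def nmse(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Normalized mean squared error ``||x_hat - x||^2 / ||x||^2``."""
    x_hat, x = np.asarray(x_hat, float), np.asarray(x, float)
    if x_hat.shape != x.shape:
        raise ValueError("shape mismatch")
    energy = float((x ** 2).sum())
    if energy == 0:
        raise ValueError("reference signal has zero energy")
    return float(((x_hat - x) ** 2).sum() / energy)


def pcc(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Per-channel Pearson correlation, averaged across the montage.

    Channels that are constant in either signal carry no correlation and are
    excluded with a warning.
    """
    x_hat, x = np.atleast_2d(np.asarray(x_hat, float)), np.atleast_2d(np.asarray(x, float))
    if x_hat.shape != x.shape:
        raise ValueError("shape mismatch")
    vals = []
    for c in range(x.shape[0]):
        a, b = x_hat[c], x[c]
        if a.std() == 0 or b.std() == 0:
            warnings.warn(f"channel {c} constant; excluded from PCC", stacklevel=2)
            continue
        vals.append(float(np.corrcoef(a, b)[0, 1]))
    if not vals:
        raise ValueError("all channels constant; PCC undefined")
    return float(np.mean(vals))


def _gaussian_window(n: int, sigma: float) -> np.ndarray:
    w = sps.windows.gaussian(n, sigma)
    return w / w.sum()


def ssim(x_hat: np.ndarray, x: np.ndarray, win_len: int = 11,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """1-D sliding-window SSIM per channel, averaged over windows and channels.

    Local means/variances come from a Gaussian window; the stabilizers are
    ``c1 = (k1 R)^2`` and ``c2 = (k2 R)^2`` with R the dynamic range of the
    reference.  If the signal is shorter than the window, a single global
    window is used.
    """
    x_hat, x = np.atleast_2d(np.asarray(x_hat, float)), np.atleast_2d(np.asarray(x, float))
    if x_hat.shape != x.shape:
        raise ValueError("shape mismatch")
    R = float(x.max() - x.min())
    if R == 0:
        R = 1.0
    c1, c2 = (k1 * R) ** 2, (k2 * R) ** 2
    L = x.shape[1]
    if L < win_len:
        w = np.full(L, 1.0 / L)
    else:
        w = _gaussian_window(win_len, sigma)

    def filt(v):
        return np.apply_along_axis(lambda row: np.convolve(row, w, mode="valid"), 1, v)

    mu1, mu2 = filt(x_hat), filt(x)
    mu1_sq, mu2_sq, mu12 = mu1 ** 2, mu2 ** 2, mu1 * mu2
    s1 = filt(x_hat ** 2) - mu1_sq
    s2 = filt(x ** 2) - mu2_sq
    s12 = filt(x_hat * x) - mu12
    ssim_map = ((2 * mu12 + c1) * (2 * s12 + c2)) / ((mu1_sq + mu2_sq + c1) * (s1 + s2 + c2))
    return float(ssim_map.mean())


def psnr(x_hat: np.ndarray, x: np.ndarray, max_val: float = 1.0) -> float:
    """Peak SNR in dB with MAX=1 for normalized signals; +inf when exact."""
    x_hat, x = np.asarray(x_hat, float), np.asarray(x, float)
    mse = float(((x_hat - x) ** 2).mean())
    if mse == 0:
        return PSNR_INF_SENTINEL
    return float(10 * np.log10(max_val ** 2 / mse))


def snr(x_hat: np.ndarray, x: np.ndarray) -> float:
    """Signal-to-error ratio ``10 log10(||x||^2 / ||x_hat - x||^2)`` in dB."""
    x_hat, x = np.asarray(x_hat, float), np.asarray(x, float)
    err = float(((x_hat - x) ** 2).sum())
    if err == 0:
        return PSNR_INF_SENTINEL
    return float(10 * np.log10((x ** 2).sum() / err))


def topo_smoothness(x_hat: np.ndarray, montage: Montage, k: int = 4) -> float:
    """Mean squared graph-Laplacian residual over channels and time.

    Each channel's residual at a time sample is its value minus the mean of
    its k nearest neighbours (great-circle distance); spatially smooth fields
    score low.
    """
    x_hat = np.atleast_2d(np.asarray(x_hat, float))
    C = x_hat.shape[0]
    if C < k + 1:
        raise ValueError(f"need more than k+1={k + 1} channels, got {C}")
    pos = montage.positions
    d = great_circle_distance(pos[:, None, :], pos[None, :, :])
    np.fill_diagonal(d, np.inf)
    neigh = np.argsort(d, axis=1)[:, :k]
    resid = x_hat - x_hat[neigh].mean(axis=1)
    return float((resid ** 2).mean())


def _welch(x: np.ndarray, rate: float):
    L = x.shape[-1]
    nperseg = min(L, 256)
    return sps.welch(x, fs=rate, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2, axis=-1)


def bandpower_mae(x_hat: np.ndarray, x: np.ndarray, rate: float,
                  bands: dict[str, tuple[float, float]] | None = None) -> dict[str, float]:
    """Per-band mean absolute error of log band powers, averaged over channels.

    Band power is the integral of the Welch PSD over the band.
    """
    bands = bands or BANDS
    x_hat, x = np.atleast_2d(np.asarray(x_hat, float)), np.atleast_2d(np.asarray(x, float))
    f, p_hat = _welch(x_hat, rate)
    _, p_ref = _welch(x, rate)
    out = {}
    for name, (lo, hi) in bands.items():
        if hi > rate / 2:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) exceeds Nyquist")
        mask = (f >= lo) & (f <= hi)
        if not mask.any():
            raise ValueError(f"band {name} contains no frequency bins")
        bp_hat = np.trapezoid(p_hat[:, mask], f[mask], axis=1)
        bp_ref = np.trapezoid(p_ref[:, mask], f[mask], axis=1)
        out[name] = float(np.abs(np.log(bp_hat + 1e-300) - np.log(bp_ref + 1e-300)).mean())
    return out


def imag_coherence(x_hat: np.ndarray, rate: float,
                   band: tuple[float, float] | None = None) -> float:
    """Mean absolute imaginary coherency over channel pairs and band bins."""
    x_hat = np.atleast_2d(np.asarray(x_hat, float))
    C = x_hat.shape[0]
    if C < 2:
        raise ValueError("imaginary coherence needs at least 2 channels")
    L = x_hat.shape[1]
    nperseg = min(L, 256)
    f, s_auto = sps.welch(x_hat, fs=rate, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2, axis=-1)
    mask = np.ones_like(f, dtype=bool) if band is None else (f >= band[0]) & (f <= band[1])
    vals = []
    for i in range(C):
        for j in range(i + 1, C):
            _, s_ij = sps.csd(x_hat[i], x_hat[j], fs=rate, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2)
            coh = s_ij / np.sqrt(s_auto[i] * s_auto[j] + 1e-300)
            vals.append(np.abs(coh.imag[mask]).mean())
    return float(np.mean(vals))


def frechet_distance(mu1: np.ndarray, sigma1: np.ndarray,
                     mu2: np.ndarray, sigma2: np.ndarray) -> float:
    """Fréchet distance between two Gaussians:
    ``||mu1 - mu2||^2 + Tr(S1 + S2 - 2 (S1 S2)^{1/2})``.

    The cross square root is computed as ``S1^{1/2} S2 S1^{1/2}`` via
    symmetric eigendecomposition with negative eigenvalues clipped at zero.
    """
    mu1, mu2 = np.atleast_1d(np.asarray(mu1, float)), np.atleast_1d(np.asarray(mu2, float))
    sigma1, sigma2 = np.atleast_2d(np.asarray(sigma1, float)), np.atleast_2d(np.asarray(sigma2, float))
    for s in (sigma1, sigma2):
        if not np.allclose(s, s.T, atol=1e-8):
            raise ValueError("covariance matrices must be symmetric")

    def psd_sqrt(s):
        w, v = np.linalg.eigh((s + s.T) / 2)
        return (v * np.sqrt(np.clip(w, 0, None))) @ v.T

    root1 = psd_sqrt(sigma1)
    cross = psd_sqrt(root1 @ sigma2 @ root1)
    diff = mu1 - mu2
    return float(diff @ diff + np.trace(sigma1 + sigma2 - 2 * cross))


class RandomConvFeatureExtractor:
    """Fixed-seed random convolutional encoder mapping a window to a feature
    vector.

    A synthetic stand-in embedding: random band-mixing filters, tanh
    nonlinearity and temporal pooling.  It is *not* a trained EEG feature
    extractor — it only provides a deterministic, content-sensitive space in
    which the Fréchet distance can be computed; any callable with the same
    signature can replace it.
    """

    def __init__(self, n_features: int = 32, kernel: int = 9, seed: int = 1234):
        self.n_features, self.kernel, self.seed = n_features, kernel, seed
        self._filters = None

    def __call__(self, window_data: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(window_data, float))
        C, L = x.shape
        if self._filters is None or self._filters.shape[1] != C:
            rng = np.random.default_rng(self.seed)
            self._filters = rng.normal(0, 1.0 / np.sqrt(C * self.kernel),
                                       size=(self.n_features, C, self.kernel))
        feats = np.empty(self.n_features)
        for i, filt in enumerate(self._filters):
            acc = np.zeros(L - self.kernel + 1)
            for c in range(C):
                acc += np.convolve(x[c], filt[c], mode="valid")
            feats[i] = np.tanh(acc).mean()
        return feats


def eeg_fid(real_windows, fake_windows, extractor=None) -> float:
    """Fréchet distance between Gaussian fits of feature embeddings.

    ``real_windows``/``fake_windows`` are sequences of (C, L) arrays or
    objects with a ``data`` attribute; ``extractor`` maps one window to a
    fixed-length feature vector (default: the random conv stand-in).
    """
    extractor = extractor or RandomConvFeatureExtractor()

    def embed(ws):
        if len(ws) < 2:
            raise ValueError("need at least 2 windows per side")
        return np.stack([extractor(getattr(w, "data", w)) for w in ws])

    fr, fk = embed(real_windows), embed(fake_windows)
    return frechet_distance(fr.mean(0), np.cov(fr, rowvar=False),
                            fk.mean(0), np.cov(fk, rowvar=False))


def evaluate_pair(x_hat: np.ndarray, x: np.ndarray, rate: float,
                  montage: Montage | None = None) -> MetricReport:
    """Compute the full metric suite for one reconstruction/reference pair."""
    report = MetricReport(
        nmse=nmse(x_hat, x),
        pcc=pcc(x_hat, x),
        ssim=ssim(x_hat, x),
        psnr_db=psnr(x_hat, x),
        snr_db=snr(x_hat, x),
        bandpower_mae=bandpower_mae(
            x_hat, x, rate,
            {k: v for k, v in BANDS.items() if v[1] < rate / 2}),
        meta={"welch": "hann, nperseg=min(L,256), 50% overlap",
              "ssim": "gaussian win 11, sigma 1.5, K1=0.01, K2=0.03",
              "psnr_max": 1.0},
    )
    if montage is not None and len(montage) >= 5:
        report.topo_smoothness = topo_smoothness(x_hat, montage)
    if x_hat.shape[0] >= 2:
        report.imag_coherence = imag_coherence(x_hat, rate)
    return report
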
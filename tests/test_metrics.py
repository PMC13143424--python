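"""Metric-suite oracles: hand values, cross-implementation checks, identities."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as sk_ssim

from eegsr.metrics import (RandomConvFeatureExtractor, bandpower_mae, eeg_fid,
                           evaluate_pair, frechet_distance, imag_coherence,
                           nmse, pcc, psnr, snr, ssim, topo_smoothness,
                           PSNR_INF_SENTINEL)


def test_nmse_hand_values(rng):
    x = rng.normal(size=(4, 64))
    assert nmse(x, x) == 0.0
    assert nmse(np.zeros_like(x), x) == pytest.approx(1.0)
    assert nmse(np.array([1.0, 1.0]), np.array([1.0, 2.0])) == pytest.approx(0.2)
    with pytest.raises(ValueError, match="zero energy"):
        nmse(x, np.zeros_like(x))


def test_pcc_affine_invariance_and_formula_oracle(rng):
    x = rng.normal(size=(4, 64))
    assert pcc(2 * x + 3, x) == pytest.approx(1.0)
    assert pcc(-x, x) == pytest.approx(-1.0)
    y = rng.normal(size=(4, 64))
    direct = np.mean([
        np.cov(y[c], x[c])[0, 1] / (y[c].std(ddof=1) * x[c].std(ddof=1))
        for c in range(4)])
    assert pcc(y, x) == pytest.approx(direct, abs=1e-10)


def test_pcc_warns_and_excludes_constant_channels(rng):
    x = rng.normal(size=(3, 32))
    y = x.copy()
    y[0] = 5.0
    with pytest.warns(UserWarning, match="constant"):
        val = pcc(y, x)
    assert val == pytest.approx(1.0)


def test_ssim_ideal_and_mean_shift(rng):
    x = rng.normal(size=(3, 128))
    assert ssim(x, x) == pytest.approx(1.0)
    assert ssim(x + 10.0, x) < 1.0


def test_ssim_matches_skimage_per_channel(rng):
    """Cross-implementation oracle: each channel treated as a 1-D image with
    a Gaussian window, sigma 1.5."""
    x = rng.normal(size=(4, 256))
    y = x + 0.4 * rng.normal(size=(4, 256))
    ours = ssim(y, x)
    R = x.max() - x.min()
    theirs = np.mean([
        sk_ssim(y[c], x[c], win_size=11, gaussian_weights=True, sigma=1.5,
                use_sample_covariance=False, data_range=R)
        for c in range(4)])
    assert ours == pytest.approx(theirs, abs=1e-6)


def test_psnr_hand_values(rng):
    x = np.zeros((1, 100))
    y_01 = x + 0.1  # MSE = 0.01
    assert psnr(y_01, x) == pytest.approx(20.0)
    y_1 = x + 1.0  # MSE = 1
    assert psnr(y_1, x) == pytest.approx(0.0)
    assert psnr(x, x) == PSNR_INF_SENTINEL


def test_snr_hand_values(rng):
    x = rng.normal(size=(2, 64))
    assert snr(np.zeros_like(x), x) == pytest.approx(0.0)  # error = signal
    assert snr(2 * x, x) == pytest.approx(0.0)  # error energy = signal energy
    y = x + 0.1 * rng.normal(size=x.shape)
    direct = 10 * np.log10((x ** 2).sum() / ((y - x) ** 2).sum())
    assert snr(y, x) == pytest.approx(direct, abs=1e-12)


def test_snr_nmse_identity(rng):
    x = rng.normal(size=(4, 64))
    y = x + 0.3 * rng.normal(size=x.shape)
    assert snr(y, x) == pytest.approx(-10 * np.log10(nmse(y, x)), abs=1e-10)


def test_topo_smoothness_properties(montage64, rng):
    const = np.ones((64, 10))
    assert topo_smoothness(const, montage64) == pytest.approx(0.0)
    smooth = np.tile(montage64.positions[:, 2][:, None], (1, 10))
    perm = np.random.default_rng(1).permutation(64)
    assert topo_smoothness(smooth, montage64) < topo_smoothness(smooth[perm], montage64)
    x = rng.normal(size=(64, 5))
    assert topo_smoothness(2 * x, montage64) == pytest.approx(
        4 * topo_smoothness(x, montage64))


def test_topo_smoothness_needs_enough_channels(montage64):
    with pytest.raises(ValueError, match="channels"):
        topo_smoothness(np.zeros((3, 4)), montage64.subset([0, 1, 2]))


def test_bandpower_mae_hand_cases(rng):
    rate = 160.0
    x = rng.normal(size=(4, 320))
    zero = bandpower_mae(x, x, rate)
    assert all(v == pytest.approx(0.0) for v in zero.values())
    doubled = bandpower_mae(2 * x, x, rate)
    assert all(v == pytest.approx(np.log(4.0), abs=1e-9) for v in doubled.values())
    t = np.arange(320) / rate
    tone10 = np.sin(2 * np.pi * 10 * t)[None, :]
    tone20 = np.sin(2 * np.pi * 20 * t)[None, :]
    mae = bandpower_mae(tone10, tone20, rate)
    assert mae["alpha"] > 5 * mae["delta"]


def test_bandpower_mae_rejects_bad_bands(rng):
    with pytest.raises(ValueError):
        bandpower_mae(np.zeros((1, 64)), np.zeros((1, 64)), 40.0,
                      {"gamma": (30.0, 50.0)})


def test_imag_coherence_zero_lag_and_quadrature():
    rate, n = 160.0, 1600
    t = np.arange(n) / rate
    a = np.sin(2 * np.pi * 10 * t)
    same = np.stack([a, a])
    assert imag_coherence(same, rate, band=(8, 13)) == pytest.approx(0.0, abs=1e-9)
    quad = np.stack([a, np.sin(2 * np.pi * 10 * t + np.pi / 2)])
    assert imag_coherence(quad, rate, band=(9, 11)) > 0.9
    # invariant to common amplitude scaling
    assert imag_coherence(5 * quad, rate, band=(9, 11)) == pytest.approx(
        imag_coherence(quad, rate, band=(9, 11)), abs=1e-12)


def test_frechet_distance_closed_forms(rng):
    mu = rng.normal(size=5)
    A = rng.normal(size=(5, 5))
    sigma = A @ A.T
    assert frechet_distance(mu, sigma, mu, sigma) == pytest.approx(0.0, abs=1e-8)
    # 1-D closed form: (mu diff)^2 + (sigma diff)^2
    d = frechet_distance(np.array([1.0]), np.array([[4.0]]),
                         np.array([3.0]), np.array([[1.0]]))
    assert d == pytest.approx((3 - 1) ** 2 + (2 - 1) ** 2)
    with pytest.raises(ValueError, match="symmetric"):
        frechet_distance(mu, A, mu, sigma)


def test_frechet_distance_matches_eigendecomposition_oracle(rng):
    """Alternative closed form via sqrt(S2) S1 sqrt(S2)."""
    A = rng.normal(size=(5, 5))
    B = rng.normal(size=(5, 5))
    s1, s2 = A @ A.T, B @ B.T
    mu1, mu2 = rng.normal(size=5), rng.normal(size=5)

    def sym_sqrt(m):
        w, v = np.linalg.eigh(m)
        return (v * np.sqrt(np.clip(w, 0, None))) @ v.T

    r2 = sym_sqrt(s2)
    cross = sym_sqrt(r2 @ s1 @ r2)
    oracle = float((mu1 - mu2) @ (mu1 - mu2)
                   + np.trace(s1 + s2 - 2 * cross))
    assert frechet_distance(mu1, s1, mu2, s2) == pytest.approx(oracle, abs=1e-8)


def test_eeg_fid_properties(rng):
    ws = [rng.normal(size=(8, 64)) for _ in range(40)]
    extractor = RandomConvFeatureExtractor(n_features=8)
    assert eeg_fid(ws, list(ws), extractor) == pytest.approx(0.0, abs=1e-8)
    # permutation invariance
    perm = [ws[i] for i in np.random.default_rng(2).permutation(40)]
    assert eeg_fid(ws, perm, extractor) == pytest.approx(0.0, abs=1e-8)
    # monotone in jitter scale
    vals = []
    for scale in (0.05, 0.2, 0.8):
        jit = [w + scale * rng.normal(size=w.shape) for w in ws]
        vals.append(eeg_fid(ws, jit, extractor))
    assert vals[0] < vals[1] < vals[2]
    assert all(v >= 0 for v in vals)
    with pytest.raises(ValueError, match="2 windows"):
        eeg_fid(ws[:1], ws, extractor)


def test_metrics_are_permutation_invariant_to_channel_order(montage64, rng):
    x = rng.normal(size=(64, 160))
    y = x + 0.2 * rng.normal(size=x.shape)
    perm = np.random.default_rng(3).permutation(64)
    assert nmse(y[perm], x[perm]) == pytest.approx(nmse(y, x))
    assert pcc(y[perm], x[perm]) == pytest.approx(pcc(y, x))
    assert ssim(y[perm], x[perm]) == pytest.approx(ssim(y, x))
    m_perm = montage64.subset(perm)
    assert topo_smoothness(y[perm], m_perm) == pytest.approx(
        topo_smoothness(y, montage64))


def test_evaluate_pair_ideal_values(montage64, rng):
    x = rng.normal(size=(64, 160))
    rep = evaluate_pair(x, x, rate=80.0, montage=montage64)
    assert rep.nmse == 0.0
    assert rep.pcc == pytest.approx(1.0)
    assert rep.ssim == pytest.approx(1.0)
    assert rep.psnr_db == PSNR_INF_SENTINEL
    assert all(v == pytest.approx(0.0) for v in rep.bandpower_mae.values())
    d = rep.to_dict()
    assert set(d) >= {"nmse", "pcc", "ssim", "psnr_db", "snr_db"}
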
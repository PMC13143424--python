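import numpy as np
import pytest

from eegsr.montage import build_standard_montage, select_lr_subset
from eegsr.preprocess import (FilterSpec, Recording, SplitSpec, apply_filters,
                              degrade_spatial, degrade_temporal,
                              detect_bad_channels, reject_or_repair,
                              segment_and_split, spherical_spline_reconstruct,
                              spline_upsample_baseline, upsample_to_hr_shape,
                              zscore)
from eegsr.metrics import nmse
from eegsr.synthetic import SyntheticConfig, generate_synthetic_dataset
from eegsr.windows import EEGWindow, SRTaskSpec


def _window(data, rate=160.0, montage=None):
    data = np.asarray(data, float)
    montage = montage or build_standard_montage(data.shape[0])
    return EEGWindow(data=data, rate=rate, duration=data.shape[1] / rate,
                     label=0, montage=montage)


# -- bad channels ------------------------------------------------------------

def test_bad_channel_rules(rng):
    n = 320
    data = np.stack([
        np.zeros(n),                                   # flatline
        rng.normal(size=n),                            # good
        5.0 + 1e-9 * rng.standard_normal(n),           # saturation
    ])
    data = np.vstack([data, rng.normal(size=(5, n))])
    flags = detect_bad_channels(_window(data))
    assert flags[0] == "flatline"
    assert flags[1] == "good"
    assert flags[2] == "saturation"
    assert all(f == "good" for f in flags[3:])


def test_rejection_above_thirty_percent(rng):
    montage = build_standard_montage(64)
    data = rng.normal(size=(64, 64))
    data[:20] = 0.0  # 31.25% bad
    w = _window(data, montage=montage)
    assert reject_or_repair(w, detect_bad_channels(w)) is None


def test_no_bad_channels_returns_window_unchanged(rng):
    w = _window(rng.normal(size=(16, 64)))
    out = reject_or_repair(w, detect_bad_channels(w))
    assert out is w


def test_single_bad_channel_is_repaired_in_place(rng):
    montage = build_standard_montage(64)
    data = rng.normal(size=(64, 32))
    data[5] = 0.0
    w = _window(data, montage=montage)
    out = reject_or_repair(w, detect_bad_channels(w))
    diff_mask = np.any(out.data != data, axis=1)
    assert diff_mask[5] and not diff_mask[np.arange(64) != 5].any()


def test_all_channels_bad_is_rejected_not_an_error():
    w = _window(np.zeros((8, 32)))
    assert reject_or_repair(w, detect_bad_channels(w)) is None


# -- spherical splines -------------------------------------------------------

def test_spline_reproduces_constant_fields(montage64):
    data = np.full((64, 4), 2.5)
    rec = spherical_spline_reconstruct(data, np.arange(60), np.arange(60, 64),
                                       montage64)
    assert np.abs(rec - 2.5).max() < 1e-8


def test_spline_recovers_first_harmonic_at_held_out_electrodes(montage64):
    field = montage64.positions[:, 2][:, None] * np.ones((1, 3))
    held = np.array([5, 20, 40, 60])
    good = np.setdiff1d(np.arange(64), held)
    rec = spherical_spline_reconstruct(field, good, held, montage64)
    rel = np.abs(rec - field[held]) / np.abs(field[held])
    assert rel.max() < 1e-2


def test_spline_interpolates_observed_sites_with_zero_ridge(montage64, rng):
    data = rng.normal(size=(64, 2))
    rec = spherical_spline_reconstruct(data, np.arange(64), np.array([11]),
                                       montage64, lam=0.0)
    assert np.abs(rec - data[11]).max() < 1e-6


def test_spline_needs_four_good_electrodes(montage64):
    with pytest.raises(ValueError, match="4"):
        spherical_spline_reconstruct(np.zeros((64, 1)), np.arange(3),
                                     np.array([10]), montage64)


def test_spline_error_shrinks_with_montage_density():
    """Interpolation of a smooth harmonic improves from 16 to 64 electrodes."""
    errs = {}
    for n in (16, 64):
        m = build_standard_montage(n)
        field = (m.positions[:, 2] ** 2 - m.positions[:, 0])[:, None]
        held = np.arange(0, n, n // 4)[:4]
        good = np.setdiff1d(np.arange(n), held)
        rec = spherical_spline_reconstruct(field, good, held, m)
        errs[n] = np.abs(rec - field[held]).mean()
    assert errs[64] < errs[16]


# -- filtering ---------------------------------------------------------------

def test_filter_probe_tones():
    rate, n = 160.0, 4800
    t = np.arange(n) / rate
    spec = FilterSpec(notch_hz=50.0, band_lo=0.5, band_hi=40.0)
    tone50 = np.sin(2 * np.pi * 50.0 * t)[None, :]
    tone10 = np.sin(2 * np.pi * 10.0 * t)[None, :]
    out50 = apply_filters(tone50, rate, spec)
    out10 = apply_filters(tone10, rate, spec)
    rms = lambda x: np.sqrt((x ** 2).mean())
    assert rms(out50) < 0.05 * rms(tone50)
    assert abs(rms(out10) - rms(tone10)) < 0.1 * rms(tone10)
    np.testing.assert_allclose(apply_filters(np.zeros((2, n)), rate, spec), 0.0)


def test_filter_is_linear(rng):
    rate, n = 160.0, 2400
    spec = FilterSpec(band_lo=1.0, band_hi=40.0)
    x, y = rng.normal(size=(2, n)), rng.normal(size=(2, n))
    lhs = apply_filters(2.0 * x - 3.0 * y, rate, spec)
    rhs = 2.0 * apply_filters(x, rate, spec) - 3.0 * apply_filters(y, rate, spec)
    np.testing.assert_allclose(lhs, rhs, atol=1e-8)


def test_infeasible_passband_raises():
    with pytest.raises(ValueError, match="infeasible"):
        apply_filters(np.zeros((1, 1000)), 40.0, FilterSpec(band_lo=1.0, band_hi=30.0))


# -- z-scoring ---------------------------------------------------------------

def test_zscore_hand_computed_case():
    w = _window(np.array([[1.0, 2.0, 3.0]]), rate=3.0)
    out = zscore(w)
    sigma = np.sqrt(2.0 / 3.0)  # population sigma of [1, 2, 3]
    expected = np.array([-1.0, 0.0, 1.0]) / (sigma + 1e-8)
    np.testing.assert_allclose(out.data[0], [-1.22474, 0.0, 1.22474], atol=1e-4)
    np.testing.assert_allclose(out.data[0], expected, atol=1e-12)


def test_zscore_moments_and_constant_guard(rng):
    data = np.vstack([rng.normal(2.0, 5.0, size=64), np.full(64, 7.0)])
    out = zscore(_window(data, rate=32.0))
    assert abs(out.data[0].mean()) < 1e-10
    assert abs(out.data[0].std() - 1.0) < 1e-6
    np.testing.assert_array_equal(out.data[1], 0.0)


def test_zscore_common_average_reference(rng):
    data = rng.normal(size=(4, 64)) + 10.0
    out = zscore(_window(data, rate=32.0), common_average=True)
    assert out.data.shape == data.shape


# -- windowing and splitting -------------------------------------------------

def test_segmentation_arithmetic_and_split_fractions(rng, montage16):
    rec = Recording(data=rng.normal(size=(16, 1600)), rate=160.0,
                    montage=montage16)
    train, val, test = segment_and_split(rec, duration=2.0,
                                         split=SplitSpec(seed=1))
    assert len(train) + len(val) + len(test) == 5
    assert all(w.n_samples == 320 for w in train + val + test)

    rec100 = Recording(data=rng.normal(size=(16, 320 * 100)), rate=160.0,
                       montage=montage16)
    tr, va, te = segment_and_split(rec100, duration=2.0, split=SplitSpec(seed=1))
    assert (len(tr), len(va), len(te)) == (80, 10, 10)
    tr2, va2, te2 = segment_and_split(rec100, duration=2.0, split=SplitSpec(seed=1))
    for a, b in zip(tr + va + te, tr2 + va2 + te2):
        np.testing.assert_array_equal(a.data, b.data)


def test_too_short_recording_raises(rng, montage16):
    rec = Recording(data=rng.normal(size=(16, 700)), rate=160.0,
                    montage=montage16)
    with pytest.raises(ValueError, match="at least 3"):
        segment_and_split(rec, duration=2.0, split=SplitSpec())


# -- degradation and naive upsampling ---------------------------------------

def test_spatial_degradation_and_projection_idempotence(rng, montage64):
    idx = select_lr_subset(montage64, 8)
    task = SRTaskSpec(mode="spatial", factor=8, lr_channel_indices=idx,
                      hr_channels=64)
    hr = _window(rng.normal(size=(64, 320)), montage=montage64)
    lr = degrade_spatial(hr, task)
    assert lr.data.shape == (8, 320)
    np.testing.assert_array_equal(lr.data, hr.data[idx])
    lifted = upsample_to_hr_shape(lr, task, montage64)
    np.testing.assert_array_equal(lifted[idx], lr.data)
    assert np.all(lifted[np.setdiff1d(np.arange(64), idx)] == 0)
    relr = lifted[idx]
    np.testing.assert_array_equal(relr, lr.data)


def test_temporal_degradation_matches_analytic_sampling(montage16):
    rate, n = 160.0, 1600
    t = np.arange(n) / rate
    tone = np.sin(2 * np.pi * 5.0 * t)
    hr = _window(np.tile(tone, (16, 1)), rate=rate)
    task = SRTaskSpec(mode="temporal", factor=4, lr_rate=40.0, hr_rate=160.0)
    lr = degrade_temporal(hr, task)
    assert lr.rate == 40.0 and lr.n_samples == 400
    np.testing.assert_allclose(lr.data[0],
                               np.sin(2 * np.pi * 5.0 * np.arange(400) / 40.0),
                               atol=1e-12)
    task8 = SRTaskSpec(mode="temporal", factor=8, lr_rate=20.0, hr_rate=160.0)
    assert degrade_temporal(hr, task8).n_samples == 200


def test_temporal_upsample_hand_case_and_affine_exactness():
    task = SRTaskSpec(mode="temporal", factor=2, lr_rate=1.5, hr_rate=3.0)
    lr = _window(np.array([[0.0, 1.0, 0.0]]), rate=1.5)
    out = upsample_to_hr_shape(lr, task)
    np.testing.assert_allclose(out[0], [0.0, 0.5, 1.0, 0.5, 0.0, 0.0])

    ramp = np.arange(8.0)[None, :]
    task4 = SRTaskSpec(mode="temporal", factor=4, lr_rate=4.0, hr_rate=16.0)
    out = upsample_to_hr_shape(_window(ramp, rate=4.0), task4)
    expected = np.minimum(np.arange(32) / 4.0, 7.0)
    np.testing.assert_allclose(out[0], expected)


def test_degrade_upsample_degrade_is_degrade(rng, montage64, montage16):
    idx = select_lr_subset(montage64, 4)
    task = SRTaskSpec(mode="spatial", factor=4, lr_channel_indices=idx)
    hr = _window(rng.normal(size=(64, 64)), rate=32.0, montage=montage64)
    lr = degrade_spatial(hr, task)
    lifted = upsample_to_hr_shape(lr, task, montage64)
    np.testing.assert_array_equal(lifted[idx], lr.data)

    t_task = SRTaskSpec(mode="temporal", factor=2, lr_rate=16.0, hr_rate=32.0)
    hr_t = _window(rng.normal(size=(16, 64)), rate=32.0, montage=montage16)
    lr_t = degrade_temporal(hr_t, t_task)
    lifted_t = upsample_to_hr_shape(lr_t, t_task)
    relr = lifted_t[:, ::2]
    np.testing.assert_allclose(relr, lr_t.data)


def test_spline_baseline_beats_zero_padding_on_single_source(montage64):
    cfg = SyntheticConfig(n_channels=64, n_sources=1, rate=32.0, duration=2.0,
                          band_assignment=["alpha"], snr_db=20.0, n_windows=3,
                          n_classes=1, seed=5, montage=montage64)
    ws = generate_synthetic_dataset(cfg)
    idx = select_lr_subset(montage64, 2)
    task = SRTaskSpec(mode="spatial", factor=2, lr_channel_indices=idx)
    for w in ws:
        lr = degrade_spatial(w, task)
        spline = spline_upsample_baseline(lr, task, montage64)
        zp = upsample_to_hr_shape(lr, task, montage64)
        np.testing.assert_array_equal(spline[idx], lr.data)
        assert nmse(spline, w.data) < nmse(zp, w.data)


def test_spline_baseline_constant_field_is_exact(montage64):
    idx = select_lr_subset(montage64, 2)
    task = SRTaskSpec(mode="spatial", factor=2, lr_channel_indices=idx)
    w = _window(np.full((64, 8), 1.3), rate=4.0, montage=montage64)
    lr = degrade_spatial(w, task)
    out = spline_upsample_baseline(lr, task, montage64)
    np.testing.assert_allclose(out, 1.3, atol=1e-8)


def test_read_fif_recording_matches_montage_by_name(tmp_path, montage16, rng):
    """Round-trip a raw FIF file; channels are matched case-insensitively."""
    import mne

    data = rng.normal(size=(16, 320)) * 1e-5
    info = mne.create_info([n.upper() for n in montage16.names], 160.0, "eeg")
    raw = mne.io.RawArray(data, info, verbose="error")
    path = tmp_path / "rec_raw.fif"
    raw.save(path, verbose="error")
    from eegsr.preprocess import read_recording
    rec = read_recording(path, montage16)
    assert rec.rate == 160.0
    np.testing.assert_allclose(rec.data, data, rtol=1e-5, atol=1e-11)
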
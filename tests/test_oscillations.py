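"""Filtering, ripple detection, spectra and theta phase extraction."""

import numpy as np
import pytest

from hippocode.oscillations import (
    OscillationConfig,
    PowerSeries,
    bandpass,
    characterize_swr,
    descending_zero_crossings,
    detect_swr,
    detect_theta_epochs,
    mean_swr_tf,
    morlet_tf,
    multitaper_psd,
    theta_phase_series,
    windowed_rms,
)

FS = 1000.0


def _tone(freq, duration, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------


def test_bandpass_passes_in_band_rejects_out_of_band():
    x_in = _tone(160.0, 4.0)
    x_out = _tone(50.0, 4.0)
    y_in = bandpass(x_in, FS, (125.0, 250.0))
    y_out = bandpass(x_out, FS, (125.0, 250.0))
    mid = slice(1000, 3000)
    gain_in = np.sqrt(np.mean(y_in[mid] ** 2) / np.mean(x_in[mid] ** 2))
    gain_out = np.sqrt(np.mean(y_out[mid] ** 2) / np.mean(x_out[mid] ** 2))
    assert gain_in > 0.95
    assert gain_out < 1e-3


def test_bandpass_is_zero_phase():
    # a symmetric pulse stays centered after filtering
    x = np.zeros(4000)
    x[2000] = 1.0
    y = bandpass(x, FS, (125.0, 250.0))
    env = np.abs(y)
    assert abs(int(np.argmax(env)) - 2000) <= 1


# ---------------------------------------------------------------------------
# Windowed RMS
# ---------------------------------------------------------------------------


def brute_rms(x, fs, window, step):
    wlen = int(round(window * fs))
    slen = int(round(step * fs))
    out = []
    start = 0
    while start + wlen <= x.size:
        out.append(np.sqrt(np.mean(x[start : start + wlen] ** 2)))
        start += slen
    return np.array(out)


def test_windowed_rms_matches_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(100):
        n = int(rng.integers(200, 2000))
        x = rng.normal(0, 1, n)
        ps = windowed_rms(x, FS, 0.020, 0.010)
        want = brute_rms(x, FS, 0.020, 0.010)
        np.testing.assert_allclose(ps.rms, want, rtol=1e-9, atol=1e-12)


def test_windowed_rms_of_constant_signal():
    ps = windowed_rms(np.full(2000, 3.0), FS, 0.020, 0.010)
    np.testing.assert_allclose(ps.rms, 3.0, rtol=1e-12)
    assert ps.window_centers[0] == pytest.approx(0.010)
    assert ps.window_centers[1] - ps.window_centers[0] == pytest.approx(0.010)


def test_windowed_rms_baseline_restricted_to_epochs():
    x = np.concatenate([np.full(5000, 1.0), np.full(5000, 10.0)])
    ps = windowed_rms(x, FS, 0.020, 0.010, baseline_epochs=[(0.0, 5.0)])
    assert ps.mean == pytest.approx(1.0, rel=1e-6)
    assert ps.sd == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# SWR detection
# ---------------------------------------------------------------------------


def _power_series(rms, step=0.010, window=0.020):
    centers = window / 2 + step * np.arange(rms.size)
    return PowerSeries(
        window_centers=centers,
        rms=rms,
        window=window,
        step=step,
        mean=float(rms.mean()),
        sd=float(rms.std()),
    )


def test_detect_swr_single_burst():
    rms = np.ones(1000) + np.random.default_rng(0).normal(0, 0.01, 1000)
    rms[500:506] = 5.0  # huge excursion
    ps = _power_series(rms)
    epochs = detect_swr(ps, two_pass=False)
    assert len(epochs) == 1
    ep = epochs[0]
    assert ep.start < 0.010 * 500 + 0.010 < ep.end


def test_detect_swr_nothing_in_flat_noise():
    rms = np.ones(1000) + np.random.default_rng(1).normal(0, 0.01, 1000)
    assert detect_swr(_power_series(rms), two_pass=False) == []


def test_detect_swr_merges_close_epochs_and_enforces_min_duration():
    cfg = OscillationConfig()
    rms = np.ones(2000) + np.random.default_rng(2).normal(0, 0.01, 2000)
    rms[600:604] = 5.0
    rms[605:609] = 5.0  # separated by < 10 ms -> merged
    eps = detect_swr(_power_series(rms), cfg=cfg, two_pass=False)
    assert len(eps) == 1
    assert eps[0].duration >= cfg.min_swr_duration


def test_detect_swr_reference_rejection():
    rms = np.ones(1000) + np.random.default_rng(3).normal(0, 0.01, 1000)
    rms[500:506] = 5.0
    ref = np.ones(1000) + np.random.default_rng(4).normal(0, 0.01, 1000)
    ref[501:505] = 8.0  # simultaneous artifact on the reference channel
    eps = detect_swr(_power_series(rms), ref_power=_power_series(ref), two_pass=False)
    assert eps == []


# ---------------------------------------------------------------------------
# Phase extraction
# ---------------------------------------------------------------------------


def test_descending_zero_crossings_of_sine():
    # sin crosses + -> - at t = (k + 1/2) / f
    f = 8.0
    x = _tone(f, 4.0)
    cr = descending_zero_crossings(x, FS)
    spacing = np.diff(cr)
    np.testing.assert_allclose(spacing, 1.0 / f, atol=1e-3)
    np.testing.assert_allclose(cr % (1.0 / f), 0.5 / f, atol=1e-3)


def test_theta_phase_linear_between_crossings():
    f = 8.0
    x = _tone(f, 10.0)
    series = theta_phase_series(x, FS, [(0.5, 9.5)])
    # phase of sin: 0 deg at descending zero-crossing -> phase = (360 f t - 180) mod 360
    t = series.times[series.valid]
    got = series.phase_deg[series.valid]
    want = (360.0 * f * t + 180.0) % 360.0
    err = np.abs((got - want + 180.0) % 360.0 - 180.0)
    # exclude filter edge transients at the signal boundaries
    inner = (t > 1.0) & (t < 9.0)
    assert np.max(err[inner]) < 2.0


def test_phase_series_invalid_outside_epochs():
    x = _tone(8.0, 10.0)
    series = theta_phase_series(x, FS, [(2.0, 4.0)])
    outside = (series.times < 1.9) | (series.times > 4.1)
    assert not series.valid[outside].any()


# ---------------------------------------------------------------------------
# Morlet wavelets
# ---------------------------------------------------------------------------


def test_morlet_ridge_scales_as_inverse_sqrt_frequency():
    fs = 1000.0
    freqs = np.array([130.0, 200.0])
    t = np.arange(int(4 * fs)) / fs
    for i, f in enumerate(freqs):
        tf = morlet_tf(np.sin(2 * np.pi * f * t), fs, freqs)
        ridge = tf.magnitude[:, 1000:3000].max(axis=1)
        assert np.argmax(ridge) == i
    tf1 = morlet_tf(np.sin(2 * np.pi * freqs[0] * t), fs, freqs)
    tf2 = morlet_tf(np.sin(2 * np.pi * freqs[1] * t), fs, freqs)
    r1 = tf1.magnitude[0, 1000:3000].mean()
    r2 = tf2.magnitude[1, 1000:3000].mean()
    # unit-total-energy wavelets: tone response ~ f^(-1/2)
    assert r1 / r2 == pytest.approx(np.sqrt(freqs[1] / freqs[0]), rel=0.05)


def test_morlet_white_noise_row_energy_flat():
    rng = np.random.default_rng(6)
    x = rng.normal(0, 1, 20000)
    freqs = np.arange(90.0, 300.0, 30.0)
    tf = morlet_tf(x, 1000.0, freqs)
    energy = (tf.magnitude[:, 2000:-2000] ** 2).mean(axis=1)
    assert energy.max() / energy.min() < 1.3


def test_mean_swr_tf_shape_and_peak_row():
    from hippocode.oscillations import SwrEpoch

    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    x = np.random.default_rng(7).normal(0, 0.05, t.size)
    centers = [2.0, 5.0, 8.0]
    for c in centers:
        env = np.exp(-((t - c) ** 2) / (2 * 0.01**2))
        x += env * np.sin(2 * np.pi * 170.0 * (t - c))
    eps = [
        SwrEpoch(start=c - 0.03, end=c + 0.03, peak_power_time=c) for c in centers
    ]
    cfg = OscillationConfig(wavelet_freqs=(90.0, 300.0, 10.0))
    tfmap = mean_swr_tf(x, fs, eps, cfg=cfg)
    peak_row = tfmap.frequencies[np.argmax(tfmap.magnitude.max(axis=1))]
    assert abs(peak_row - 170.0) <= 10.0


# ---------------------------------------------------------------------------
# Multitaper PSD
# ---------------------------------------------------------------------------


def test_multitaper_parseval():
    rng = np.random.default_rng(8)
    x = rng.normal(0, 2.0, 4000)
    f, psd = multitaper_psd([x], FS)
    df = f[1] - f[0]
    assert np.sum(psd) * df == pytest.approx(np.var(x), rel=0.05)


def test_multitaper_peak_at_tone_frequency():
    x = _tone(7.8, 4.0) + np.random.default_rng(9).normal(0, 0.1, 4000)
    f, psd = multitaper_psd([x], FS)
    assert abs(f[np.argmax(psd)] - 7.8) < 1.0


def test_multitaper_zero_padding_refines_grid_not_power():
    x = _tone(160.0, 0.06)
    f1, p1 = multitaper_psd([x], FS, nw=1.5, k=1)
    f2, p2 = multitaper_psd([x], FS, nw=1.5, k=1, nfft=1024)
    assert f2.size > f1.size
    df1, df2 = f1[1] - f1[0], f2[1] - f2[0]
    assert np.sum(p1) * df1 == pytest.approx(np.sum(p2) * df2, rel=0.05)
    assert abs(f2[np.argmax(p2)] - 160.0) < abs(df1)


# ---------------------------------------------------------------------------
# Theta epochs
# ---------------------------------------------------------------------------


def test_theta_epochs_cover_theta_segment_only():
    rng = np.random.default_rng(10)
    # 0-10 s: delta-dominated; 10-20 s: theta-dominated
    delta = _tone(3.0, 10.0, amp=3.0) + rng.normal(0, 0.3, 10000)
    theta = _tone(8.0, 10.0, amp=3.0) + rng.normal(0, 0.3, 10000)
    x = np.concatenate([delta, theta])
    eps = detect_theta_epochs(x, FS)
    covered = sum(e - s for s, e in eps)
    in_theta = sum(max(0.0, min(e, 20.0) - max(s, 10.0)) for s, e in eps)
    assert covered > 8.0
    assert in_theta / covered > 0.95


def test_characterize_swr_peak_frequency_of_injected_ripple():
    fs = 1000.0
    t = np.arange(int(2 * fs)) / fs
    rng = np.random.default_rng(12)
    x = rng.normal(0, 0.05, t.size)
    c, carrier = 1.0, 165.0
    x += np.exp(-((t - c) ** 2) / (2 * 0.01**2)) * np.sin(2 * np.pi * carrier * (t - c))
    cfg = OscillationConfig()
    filt = bandpass(x, fs, cfg.ripple_band)
    ps = windowed_rms(filt, fs, cfg.rms_window, cfg.rms_step)
    eps = detect_swr(ps, cfg=cfg)
    assert len(eps) == 1
    ep = characterize_swr(eps[0], filt, fs, ps, cfg=cfg)
    assert ep.peak_frequency == pytest.approx(carrier, abs=8.0)
    assert ep.start <= ep.peak_power_time <= ep.end
    assert ep.amplitude > 5 * 0.05
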
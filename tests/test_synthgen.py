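"""Generator properties: determinism, trajectories, LFP and spike models."""

import numpy as np
import pytest
from scipy import special

from hippocode.oscillations import (
    OscillationConfig,
    bandpass,
    detect_theta_epochs,
    windowed_rms,
)
from hippocode.phase import circ_stats, phases_of_spikes, rayleigh_p
from hippocode.session_io import compute_speed
from hippocode.spatial import BIN_SIZE, ZigzagMaze, linearize_zigzag
from hippocode.synthgen import (
    InterneuronTuning,
    PlaceCellTuning,
    analytic_phase_series,
    gen_interneuron,
    gen_lfp,
    gen_place_cell,
    gen_trajectory,
    gen_unit_features,
    gen_waveform,
)


# ---------------------------------------------------------------------------
# Determinism
# ---------------------------------------------------------------------------


def test_trajectory_deterministic_given_seed():
    a = gen_trajectory("open_field", 30.0, 42)
    b = gen_trajectory("open_field", 30.0, 42)
    np.testing.assert_array_equal(a.x, b.x)
    np.testing.assert_array_equal(a.y, b.y)


def test_lfp_deterministic_given_seed():
    track = gen_trajectory("rest", 20.0, 0)
    c1, r1, g1 = gen_lfp(track, 1, duration=20.0)
    c2, r2, g2 = gen_lfp(track, 1, duration=20.0)
    np.testing.assert_array_equal(c1.samples, c2.samples)
    np.testing.assert_array_equal(g1.ripple_times, g2.ripple_times)


def test_session_serialization_deterministic(tmp_path, small_session):
    import filecmp

    from hippocode.session_io import write_session
    from hippocode.synthgen import gen_session

    ses1, _ = small_session
    ses2, _ = gen_session(3, trial_duration=60.0, n_pyr=6, n_int=2)
    a, b = str(tmp_path / "a"), str(tmp_path / "b")
    write_session(ses1, a)
    write_session(ses2, b)
    cmp = filecmp.dircmp(a, b)
    assert not cmp.diff_files and not cmp.left_only and not cmp.right_only


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def test_rest_trajectory_mostly_immobile():
    track = gen_trajectory("rest", 120.0, 5)
    sp = compute_speed(track)
    assert np.mean(sp.speed[sp.valid] < 3.0) >= 0.95


def test_open_field_covers_arena_in_twenty_minutes():
    track = gen_trajectory("open_field", 1200.0, 6)
    xi = np.clip((track.x / BIN_SIZE).astype(int), 0, 34)
    yi = np.clip((track.y / BIN_SIZE).astype(int), 0, 34)
    visited = np.zeros((35, 35), bool)
    visited[xi, yi] = True
    assert visited.mean() >= 0.90
    assert track.x.min() >= 0 and track.x.max() <= 70
    # speed in a plausible foraging range
    sp = compute_speed(track)
    assert 5.0 < np.nanmean(sp.speed[sp.valid]) < 25.0


def test_zigzag_trajectory_alternates_directions():
    track = gen_trajectory("zigzag", 300.0, 7)
    lin, direction, ok = linearize_zigzag(track, ZigzagMaze())
    # complete runs exist in both directions and alternate
    runs = []
    prev = 0
    for d in direction:
        if d != 0 and d != prev:
            runs.append(d)
            prev = d
        elif d == 0:
            prev = 0
    assert len(runs) >= 4
    assert all(a != b for a, b in zip(runs, runs[1:]))


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------


def test_lfp_theta_delta_ratio_tracks_behavior():
    cfg = OscillationConfig()
    run = gen_trajectory("open_field", 120.0, 8)
    rest = gen_trajectory("rest", 120.0, 9)
    c_run, _, _ = gen_lfp(run, 10, duration=120.0, ripple_rate=0.0)
    c_rest, _, _ = gen_lfp(rest, 11, duration=120.0, ripple_rate=0.0)
    eps_run = detect_theta_epochs(c_run.samples, c_run.sample_rate, cfg)
    eps_rest = detect_theta_epochs(c_rest.samples, c_rest.sample_rate, cfg)
    frac_run = sum(e - s for s, e in eps_run) / 120.0
    frac_rest = sum(e - s for s, e in eps_rest) / 120.0
    assert frac_run > 0.7
    assert frac_rest < 0.1


def test_reference_channel_has_no_ripples():
    track = gen_trajectory("rest", 300.0, 12)
    chan, ref, gt = gen_lfp(track, 13, duration=300.0)
    assert gt.ripple_times.size > 30
    cfg = OscillationConfig()
    filt = bandpass(ref.samples, ref.sample_rate, cfg.ripple_band)
    ps = windowed_rms(filt, ref.sample_rate, cfg.rms_window, cfg.rms_step)
    # no 7 SD excursions on the reference
    assert (ps.rms < ps.mean + 7 * ps.sd).mean() > 0.999


def test_injected_ripples_respect_minimum_separation():
    track = gen_trajectory("rest", 300.0, 14)
    _, _, gt = gen_lfp(track, 15, duration=300.0)
    if gt.ripple_times.size > 1:
        assert np.diff(np.sort(gt.ripple_times)).min() >= 0.25
    assert ((gt.ripple_freqs >= 130.0) & (gt.ripple_freqs <= 180.0)).all()


# ---------------------------------------------------------------------------
# Spike generators
# ---------------------------------------------------------------------------


def test_zero_rate_cell_is_silent():
    track = gen_trajectory("open_field", 30.0, 16)
    series = analytic_phase_series(8.0, 30.0)
    tuning = PlaceCellTuning(
        peak_rate=0.0, field_center=(35.0, 35.0), field_sd=6.0, baseline_rate=0.0
    )
    spikes = gen_place_cell(track, series, tuning, 17)
    assert spikes.size == 0


def test_place_cell_spikes_concentrate_in_field():
    track = gen_trajectory("open_field", 300.0, 18)
    series = analytic_phase_series(8.0, 300.0)
    tuning = PlaceCellTuning(
        peak_rate=15.0, field_center=(35.0, 35.0), field_sd=6.0, baseline_rate=0.1,
        theta_kappa=1.0,
    )
    spikes = gen_place_cell(track, series, tuning, 19)
    assert spikes.size > 50
    x = np.interp(spikes, track.times, track.x)
    y = np.interp(spikes, track.times, track.y)
    d = np.hypot(x - 35.0, y - 35.0)
    assert np.median(d) < 3 * 6.0


def test_place_cell_vector_length_matches_bessel_ratio():
    # slope 0, kappa = 1 -> R ~ I1(1)/I0(1) ~ 0.446
    track = gen_trajectory("open_field", 600.0, 20)
    series = analytic_phase_series(8.0, 600.0)
    tuning = PlaceCellTuning(
        peak_rate=12.0, field_center=(35.0, 35.0), field_sd=10.0,
        baseline_rate=0.0, theta_kappa=1.0, theta_phase0=120.0,
        precession_slope=0.0,
    )
    spikes = gen_place_cell(track, series, tuning, 21)
    phases, _ = phases_of_spikes(spikes, series)
    assert phases.size > 500
    s = circ_stats(phases)
    want = special.i1(1.0) / special.i0(1.0)
    assert s.vector_length == pytest.approx(want, abs=0.05)
    assert abs((s.mean_phase - 120.0 + 180) % 360 - 180) < 15.0


def test_interneuron_mean_rate_within_ten_percent():
    series = analytic_phase_series(8.0, 600.0)
    tuning = InterneuronTuning(baseline_rate=25.0, theta_kappa=0.5)
    spikes = gen_interneuron(series, tuning, 22, (0.0, 600.0))
    assert spikes.size / 600.0 == pytest.approx(25.0, rel=0.10)


def test_unmodulated_interneuron_flat_phase_histogram():
    series = analytic_phase_series(8.0, 300.0)
    tuning = InterneuronTuning(baseline_rate=30.0, theta_kappa=0.0)
    spikes = gen_interneuron(series, tuning, 23, (0.0, 300.0))
    phases, _ = phases_of_spikes(spikes, series)
    s = circ_stats(phases)
    # Rayleigh: no significant modulation
    assert rayleigh_p(phases.size, s.vector_length) > 0.01


def test_theta_modulated_interneuron_strongly_locked():
    series = analytic_phase_series(8.0, 300.0)
    tuning = InterneuronTuning(baseline_rate=30.0, theta_kappa=1.0, theta_phase0=200.0)
    spikes = gen_interneuron(series, tuning, 24, (0.0, 300.0))
    phases, _ = phases_of_spikes(spikes, series)
    s = circ_stats(phases)
    assert rayleigh_p(phases.size, s.vector_length) < 1e-6
    assert abs((s.mean_phase - 200.0 + 180) % 360 - 180) < 10.0


def test_waveform_width_calibrated_to_target():
    from hippocode.units import spike_duration_at_25pct

    rng = np.random.default_rng(25)
    for target in (0.15, 0.25, 0.36):
        w, rate = gen_waveform(target, rng)
        got = spike_duration_at_25pct(w, rate)
        assert got == pytest.approx(target, rel=0.01)


def test_feature_clusters_are_separated():
    feats, labels = gen_unit_features(20, 5, 26)
    assert labels.count("pyramidal") == 20
    pyr = feats[:20]
    intn = feats[20:]
    # interneurons fire faster and spike narrower than pyramidal cells
    assert 10 ** intn[:, 0].min() > 10 ** pyr[:, 0].max()
    assert intn[:, 2].max() < pyr[:, 2].min()
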
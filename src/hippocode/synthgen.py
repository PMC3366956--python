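"""Synthetic recording sessions with known ground truth.

Every analysis stage in this package has a recovery test: the generator
produces trajectories (open field, zigzag maze, rest box), a 1 kHz LFP with
pink-noise background, speed-gated theta and immobility-locked ripple
bursts, and spike trains from place cells (Gaussian spatial tuning, von
Mises theta coupling, optional phase precession, SWR gain) and
interneurons.  All generators are pure functions of (parameters, seed) and
the injected events/tuning are returned as :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .oscillations import OscillationConfig, PhaseSeries, bandpass
from .session_io import (
    LfpSignal,
    PositionTrack,
    RecordingSession,
    TrialEpoch,
    Unit,
    compute_speed,
)
from .spatial import ZigzagMaze

__all__ = [
    "GroundTruth",
    "PlaceCellTuning",
    "InterneuronTuning",
    "gen_trajectory",
    "gen_lfp",
    "gen_place_cell",
    "gen_interneuron",
    "gen_session",
    "gen_unit_features",
    "gen_waveform",
    "gen_precessing_field",
    "analytic_phase_series",
]

LFP_RATE = 1000.0  # Hz; the ripple band is fully represented at 1 kHz
TRACK_RATE = 25.0  # Hz camera frame rate
OPEN_FIELD = (70.0, 70.0)  # cm
REST_BOX = (23.0, 25.0)  # cm

# Unit-feature clusters (log10 rate [Hz], autocorr first moment [ms],
# spike duration [ms]).  The pyramidal cluster is deliberately tight so
# that interneurons sit far away in template-SD units, as in real CA1
# populations where the classification thresholds are absolute distances.
PYR_FEATURES = {"log_rate": (0.20, 0.25), "ac_moment": (12.5, 0.8), "duration": (0.36, 0.004)}
INT_FEATURES = {"log_rate": (1.45, 0.12), "ac_moment": (11.0, 1.0), "duration": (0.15, 0.010)}


@dataclass
class PlaceCellTuning:
    peak_rate: float  # Hz at field center
    field_center: tuple[float, float]  # cm (open field)
    field_sd: float  # cm
    baseline_rate: float = 0.2  # Hz everywhere (lets the cell join SWRs)
    theta_kappa: float = 1.5
    theta_phase0: float = 180.0  # deg preferred phase at field entry
    precession_slope: float = 0.0  # cycles per field traversal
    swr_gain: float = 8.0
    linear_center: float | None = None  # cm along the zigzag skeleton
    linear_sd: float = 8.0
    direction: int = 1  # +1 northbound, -1 southbound


@dataclass
class InterneuronTuning:
    baseline_rate: float  # Hz
    theta_kappa: float = 0.5
    theta_phase0: float = 90.0
    ripple_kappa: float = 1.0
    ripple_phase0: float = 180.0
    swr_gain: float = 2.0


@dataclass
class GroundTruth:
    seed: int
    ripple_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    ripple_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    ripple_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    ripple_duration_sd: float = 0.010
    theta_band: tuple[float, float] = (6.0, 10.0)
    place_tuning: dict[str, PlaceCellTuning] = field(default_factory=dict)
    interneuron_tuning: dict[str, InterneuronTuning] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------


def _ou_walk(
    rng: np.random.Generator,
    duration: float,
    arena: tuple[float, float],
    mean_speed: float,
    tau: float = 0.7,
    margin: float = 0.5,
    fps: float = TRACK_RATE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ornstein-Uhlenbeck velocity random walk with reflecting walls."""
    dt = 1.0 / fps
    n = int(round(duration * fps))
    # per-component stationary SD giving the requested mean 2D speed
    sd_v = mean_speed / np.sqrt(np.pi / 2)
    sigma = sd_v * np.sqrt(2 / tau)
    t = np.arange(n) / fps
    x = np.empty(n)
    y = np.empty(n)
    vx = rng.normal(0, sd_v)
    vy = rng.normal(0, sd_v)
    px = rng.uniform(margin, arena[0] - margin)
    py = rng.uniform(margin, arena[1] - margin)
    for i in range(n):
        vx += -vx / tau * dt + sigma * np.sqrt(dt) * rng.normal()
        vy += -vy / tau * dt + sigma * np.sqrt(dt) * rng.normal()
        px += vx * dt
        py += vy * dt
        if px < margin:
            px = 2 * margin - px
            vx = abs(vx)
        elif px > arena[0] - margin:
            px = 2 * (arena[0] - margin) - px
            vx = -abs(vx)
        if py < margin:
            py = 2 * margin - py
            vy = abs(vy)
        elif py > arena[1] - margin:
            py = 2 * (arena[1] - margin) - py
            vy = -abs(vy)
        x[i] = px
        y[i] = py
    return t, x, y


def _zigzag_runs(
    rng: np.random.Generator, duration: float, maze: ZigzagMaze, fps: float = TRACK_RATE
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """End-to-end runs along the maze skeleton with pauses at the ends."""
    dt = 1.0 / fps
    n = int(round(duration * fps))
    s = np.empty(n)
    pos = 0.0
    heading = 1
    pause_left = int(rng.uniform(1.0, 3.0) * fps)
    speed = 0.0
    for i in range(n):
        if pause_left > 0:
            pause_left -= 1
            pos += rng.normal(0, 0.02)  # slight jitter while eating
            pos = min(max(pos, 0.0), maze.total_length)
            if pause_left == 0:
                heading = 1 if pos < maze.total_length / 2 else -1
                speed = rng.uniform(12.0, 18.0)
        else:
            speed = np.clip(speed + rng.normal(0, 1.5), 8.0, 25.0)
            pos += heading * speed * dt
            if pos <= 0.0 or pos >= maze.total_length:
                pos = min(max(pos, 0.0), maze.total_length)
                pause_left = int(rng.uniform(1.5, 4.0) * fps)
        s[i] = pos
    xy = maze.point_at(s)
    t = np.arange(n) / fps
    return t, xy[:, 0], xy[:, 1]


def gen_trajectory(
    arena: str, duration: float, seed: int | np.random.Generator, fps: float = TRACK_RATE
) -> PositionTrack:
    """Simulated position track: ``open_field``, ``zigzag`` or ``rest``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if arena == "open_field":
        t, x, y = _ou_walk(rng, duration, OPEN_FIELD, mean_speed=12.0)
    elif arena == "zigzag":
        t, x, y = _zigzag_runs(rng, duration, ZigzagMaze())
    elif arena == "rest":
        # near-stationary jitter in the rest box
        t, x, y = _ou_walk(rng, duration, REST_BOX, mean_speed=0.6, tau=0.3, margin=8.0)
    else:
        raise ValueError(f"unknown arena {arena!r}")
    n = t.size
    return PositionTrack(times=t, x=x, y=y, valid=np.ones(n, dtype=bool))


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-amplitude noise, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _speed_at(speed_times: np.ndarray, speed: np.ndarray, t: np.ndarray) -> np.ndarray:
    s = np.where(np.isfinite(speed), speed, 0.0)
    return np.interp(t, speed_times, s)


def gen_lfp(
    track: PositionTrack,
    seed: int | np.random.Generator,
    duration: float | None = None,
    fs: float = LFP_RATE,
    ripple_rate: float = 0.3,  # events/s during immobility
    ripple_snr: float = 8.0,  # amplitude in units of ripple-band noise SD
    ripple_env_sd: float = 0.010,  # s
    ripple_carrier: tuple[float, float] = (130.0, 180.0),
    ripple_min_separation: float = 0.25,
    theta_amp_factor: float = 8.0,  # theta amplitude over delta-band noise RMS
    make_reference: bool = True,
) -> tuple[LfpSignal, LfpSignal | None, GroundTruth]:
    """Synthesize a pyramidal-layer LFP channel (plus a reference channel).

    Background is pink noise; a speed-gated theta oscillation (wandering
    6-10 Hz instantaneous frequency) rides on it during running, and ripple
    bursts (Gaussian envelope, uniform carrier frequency) are injected at
    Poisson times during immobility.  The reference channel contains no
    ripples.  Injected event times/frequencies/amplitudes are returned as
    ground truth.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration is None:
        duration = float(track.times[-1] + 1.0 / TRACK_RATE)
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    noise = _pink_noise(rng, n, fs)
    ripple_noise_sd = float(bandpass(noise, fs, (125.0, 250.0)).std())
    delta_noise_rms = float(np.sqrt(np.mean(bandpass(noise, fs, (2.0, 4.0)) ** 2)))

    sp = compute_speed(track)
    speed = _speed_at(sp.times, sp.speed, t)

    # theta: amplitude gated on running, smoothly ramped over ~250 ms
    gate = (speed > 3.0).astype(float)
    k = int(0.25 * fs)
    gate = np.convolve(gate, np.ones(k) / k, mode="same")
    inst_f = 8.0 + np.convolve(rng.normal(0, 0.6, n), np.ones(int(fs)) / fs, mode="same") * np.sqrt(fs)
    inst_f = np.clip(inst_f, 6.2, 9.8)
    phase = 2 * np.pi * np.cumsum(inst_f) / fs
    theta_amp = theta_amp_factor * delta_noise_rms * np.sqrt(2)
    theta = theta_amp * gate * np.sin(phase)

    # ripples during immobility
    n_cand = rng.poisson(ripple_rate * duration * 3)
    cand = np.sort(rng.uniform(0.1, duration - 0.1, n_cand))
    keep: list[float] = []
    for c in cand:
        if speed[int(c * fs)] < 3.0 and (not keep or c - keep[-1] >= ripple_min_separation):
            keep.append(c)
            if len(keep) >= ripple_rate * duration * 1.05:
                pass
    # thin back to the requested rate on immobility time
    immobile_time = float((speed < 3.0).mean() * duration)
    target = rng.poisson(ripple_rate * immobile_time)
    if len(keep) > target > 0:
        idx = np.sort(rng.choice(len(keep), size=target, replace=False))
        keep = [keep[i] for i in idx]
    times = np.array(keep)
    freqs = rng.uniform(*ripple_carrier, size=times.size)
    amps = np.full(times.size, ripple_snr * ripple_noise_sd)
    lfp = noise + theta
    for t0, f0, a0 in zip(times, freqs, amps):
        lo = max(int((t0 - 5 * ripple_env_sd) * fs), 0)
        hi = min(int((t0 + 5 * ripple_env_sd) * fs), n)
        tt = t[lo:hi] - t0
        lfp[lo:hi] += a0 * np.exp(-(tt**2) / (2 * ripple_env_sd**2)) * np.cos(2 * np.pi * f0 * tt)

    chan = LfpSignal(channel_id="ca1", sample_rate=fs, samples=lfp, in_pyramidal_layer=True)
    ref = None
    if make_reference:
        ref = LfpSignal(
            channel_id="ref",
            sample_rate=fs,
            samples=_pink_noise(rng, n, fs),
            in_pyramidal_layer=False,
            is_reference=True,
        )
    gt = GroundTruth(
        seed=-1,
        ripple_times=times,
        ripple_freqs=freqs,
        ripple_amplitudes=amps,
        ripple_duration_sd=ripple_env_sd,
    )
    return chan, ref, gt


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


def _phase_at(phase_series: PhaseSeries, t: np.ndarray) -> np.ndarray:
    """Phase (deg) at arbitrary times; NaN outside valid segments."""
    out = np.full(t.size, np.nan)
    for cr in phase_series.segments:
        inside = (t >= cr[0]) & (t < cr[-1])
        if not inside.any():
            continue
        pos = np.searchsorted(cr, t[inside], side="right") - 1
        out[inside] = 360.0 * (t[inside] - cr[pos]) / (cr[pos + 1] - cr[pos])
    return out


def _von_mises_factor(phase_deg: np.ndarray, kappa: float, mu_deg: np.ndarray | float) -> np.ndarray:
    """von Mises modulation with unit mean over the cycle; 1 where phase is NaN."""
    if kappa == 0:
        return np.ones_like(np.asarray(phase_deg, float))
    rad = np.deg2rad(phase_deg)
    mu = np.deg2rad(mu_deg)
    f = np.exp(kappa * np.cos(rad - mu)) / special.i0(kappa)
    return np.where(np.isnan(f), 1.0, f)


def _thin(
    rng: np.random.Generator, t0: float, t1: float, lam_max: float, rate_fn
) -> np.ndarray:
    """Exact inhomogeneous-Poisson sampling by thinning."""
    n = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n))
    if cand.size == 0:
        return cand
    u = rng.uniform(0.0, lam_max, cand.size)
    lam = rate_fn(cand)
    return cand[u < lam]


def _swr_gain_at(t: np.ndarray, swr_intervals: np.ndarray, gain: float) -> np.ndarray:
    if swr_intervals.size == 0 or gain == 1.0:
        return np.ones(t.size)
    starts = swr_intervals[:, 0]
    ends = swr_intervals[:, 1]
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, starts.size - 1)
    inside = (t >= starts[idx]) & (t < ends[idx])
    return np.where(inside, gain, 1.0)


def gen_place_cell(
    track: PositionTrack,
    phase_series: PhaseSeries,
    tuning: PlaceCellTuning,
    seed: int | np.random.Generator,
    t_range: tuple[float, float] | None = None,
    swr_intervals: np.ndarray | None = None,
    linear: np.ndarray | None = None,
    lin_direction: np.ndarray | None = None,
) -> np.ndarray:
    """Spike train of a place cell by exact Poisson thinning.

    Rate = (Gaussian spatial envelope + baseline) x von Mises theta
    modulation (preferred phase shifting linearly with relative field
    position by the precession slope) x SWR gain inside SWR intervals.
    With ``linear`` given, the envelope lives on the 1D maze coordinate;
    if ``lin_direction`` (per-track-sample run direction, +-1/0) is also
    given, the field only fires when running in the preferred direction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if t_range is None:
        t_range = (float(track.times[0]), float(track.times[-1]))
    swr = swr_intervals if swr_intervals is not None else np.empty((0, 2))

    if linear is None:

        def envelope(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            x = np.interp(t, track.times, track.x)
            y = np.interp(t, track.times, track.y)
            d2 = (x - tuning.field_center[0]) ** 2 + (y - tuning.field_center[1]) ** 2
            env = tuning.peak_rate * np.exp(-d2 / (2 * tuning.field_sd**2))
            # relative position along the travel direction through the field
            proj = np.hypot(x - tuning.field_center[0], y - tuning.field_center[1])
            rel = np.clip(0.5 + np.sign(x - tuning.field_center[0]) * proj / (4 * tuning.field_sd), 0, 1)
            return env, rel

    else:
        c = tuning.linear_center if tuning.linear_center is not None else 0.0
        w = tuning.linear_sd

        def envelope(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            s = np.interp(t, track.times, linear)
            env = tuning.peak_rate * np.exp(-((s - c) ** 2) / (2 * w**2))
            if lin_direction is not None:
                # nearest-sample run direction; field is silent off-direction
                idx = np.clip(
                    np.searchsorted(track.times, t), 1, track.times.size - 1
                )
                idx -= (t - track.times[idx - 1]) < (track.times[idx] - t)
                env = env * (lin_direction[idx] == tuning.direction)
            rel = np.clip((tuning.direction * (s - c)) / (4 * w) + 0.5, 0.0, 1.0)
            return env, rel

    def rate_fn(t: np.ndarray) -> np.ndarray:
        env, rel = envelope(t)
        ph = _phase_at(phase_series, t)
        mu = tuning.theta_phase0 + 360.0 * tuning.precession_slope * rel
        vm = _von_mises_factor(ph, tuning.theta_kappa, mu)
        g = _swr_gain_at(t, swr, tuning.swr_gain)
        return (env + tuning.baseline_rate) * vm * g

    lam_max = (
        (tuning.peak_rate + tuning.baseline_rate)
        * (np.exp(tuning.theta_kappa) / special.i0(tuning.theta_kappa) if tuning.theta_kappa else 1.0)
        * max(tuning.swr_gain, 1.0)
    )
    return _thin(rng, t_range[0], t_range[1], lam_max, rate_fn)


def gen_interneuron(
    phase_series: PhaseSeries,
    tuning: InterneuronTuning,
    seed: int | np.random.Generator,
    t_range: tuple[float, float],
    swr_intervals: np.ndarray | None = None,
    ripple_phase_series: PhaseSeries | None = None,
) -> np.ndarray:
    """Interneuron spike train: tonic rate with theta and ripple modulation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    swr = swr_intervals if swr_intervals is not None else np.empty((0, 2))

    def rate_fn(t: np.ndarray) -> np.ndarray:
        vm_t = _von_mises_factor(_phase_at(phase_series, t), tuning.theta_kappa, tuning.theta_phase0)
        lam = tuning.baseline_rate * vm_t * _swr_gain_at(t, swr, tuning.swr_gain)
        if ripple_phase_series is not None:
            vm_r = _von_mises_factor(
                _phase_at(ripple_phase_series, t), tuning.ripple_kappa, tuning.ripple_phase0
            )
            lam = lam * vm_r
        return lam

    lam_max = (
        tuning.baseline_rate
        * (np.exp(tuning.theta_kappa) / special.i0(tuning.theta_kappa) if tuning.theta_kappa else 1.0)
        * max(tuning.swr_gain, 1.0)
        * (np.exp(tuning.ripple_kappa) / special.i0(tuning.ripple_kappa) if ripple_phase_series is not None else 1.0)
    )
    return _thin(rng, t_range[0], t_range[1], lam_max, rate_fn)


# ---------------------------------------------------------------------------
# Waveforms & feature clusters
# ---------------------------------------------------------------------------


def gen_waveform(
    duration_ms: float, rng: np.random.Generator, rate: float = 96000.0
) -> tuple[np.ndarray, float]:
    """Mean spike waveform whose width at 25% amplitude equals ``duration_ms``.

    An inverted-Gaussian spike with a small late positive lobe; the
    Gaussian SD is calibrated so the measured 25% width matches the target.
    """
    from .units import spike_duration_at_25pct

    sigma_ms = duration_ms / (2 * np.sqrt(2 * np.log(4)))
    for _ in range(4):
        half = 6 * sigma_ms / 1000.0
        t = np.arange(-half, half, 1.0 / rate)
        s = sigma_ms / 1000.0
        w = -np.exp(-(t**2) / (2 * s**2)) + 0.15 * np.exp(-((t - 3.5 * s) ** 2) / (2 * (1.5 * s) ** 2))
        measured = spike_duration_at_25pct(w, rate)
        sigma_ms *= duration_ms / measured
        if abs(measured - duration_ms) / duration_ms < 1e-4:
            break
    return w * (1.0 + 0.02 * rng.normal()), rate


def gen_unit_features(
    n_pyr: int, n_int: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Sample (log10 rate, autocorr moment, duration) feature vectors for a
    population of pyramidal cells and interneurons (two separated clusters)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    labels = []
    for _ in range(n_pyr):
        p = PYR_FEATURES
        rows.append(
            [rng.normal(*p["log_rate"]), rng.normal(*p["ac_moment"]), rng.normal(*p["duration"])]
        )
        labels.append("pyramidal")
    for _ in range(n_int):
        p = INT_FEATURES
        rows.append(
            [rng.normal(*p["log_rate"]), rng.normal(*p["ac_moment"]), rng.normal(*p["duration"])]
        )
        labels.append("interneuron")
    return np.array(rows), labels


def gen_precessing_field(
    n_spikes: int,
    slope: float,
    jitter_sd_deg: float,
    seed: int | np.random.Generator,
    phase0: float = 300.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Spike (phase, relative position) pairs for one precessing field.

    Positions are drawn from the in-field firing density (Gaussian envelope
    over uniform traversal occupancy); phases follow the precession line
    ``phase0 + 360*slope*x`` with wrapped-normal jitter.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # in-field density: Gaussian envelope (center 0.5, SD 0.25) truncated to [0,1]
    x = rng.normal(0.5, 0.25, size=3 * n_spikes)
    x = x[(x >= 0) & (x <= 1)][:n_spikes]
    while x.size < n_spikes:
        extra = rng.normal(0.5, 0.25, size=n_spikes)
        x = np.concatenate([x, extra[(extra >= 0) & (extra <= 1)]])[:n_spikes]
    phases = (phase0 + 360.0 * slope * x + rng.normal(0, jitter_sd_deg, n_spikes)) % 360.0
    return phases, x


def analytic_phase_series(
    freq: float, duration: float, fs: float = LFP_RATE, t0: float = 0.0
) -> PhaseSeries:
    """Ideal phase series of a pure oscillation (for calibration tests)."""
    crossings = np.arange(t0, t0 + duration, 1.0 / freq)
    times = t0 + np.arange(int(duration * fs)) / fs
    phase = (360.0 * freq * (times - t0)) % 360.0
    valid = (times >= crossings[0]) & (times < crossings[-1])
    return PhaseSeries(times=times, phase_deg=np.where(valid, phase, np.nan), valid=valid, segments=[crossings])


# ---------------------------------------------------------------------------
# Full sessions
# ---------------------------------------------------------------------------


def gen_session(
    seed: int,
    trial_duration: float = 1200.0,
    n_pyr: int = 20,
    n_int: int = 5,
    ripple_rate: float = 0.3,
    ripple_snr: float = 8.0,
) -> tuple[RecordingSession, GroundTruth]:
    """A full nine-trial session (rest / open field / zigzag, ABAB protocol).

    Deterministic given the seed.  Pyramidal cells carry Gaussian place
    fields in the open field and precessing 1D fields on the zigzag maze;
    interneurons are tonic, theta- and ripple-modulated.  Waveforms and
    firing rates are drawn from two separated clusters so the unit
    classifier can recover the labels.
    """
    rng = np.random.default_rng(seed)
    labels_seq = ["rest", "open_field", "rest", "zigzag", "rest", "open_field", "rest", "zigzag", "rest"]
    trials: list[TrialEpoch] = []
    tracks: list[PositionTrack] = []
    t_cursor = 0.0
    for lab in labels_seq:
        tr = gen_trajectory(lab if lab != "open_field" else "open_field", trial_duration, rng)
        tracks.append(
            PositionTrack(times=tr.times + t_cursor, x=tr.x, y=tr.y, valid=tr.valid)
        )
        trials.append(TrialEpoch(lab, t_cursor, t_cursor + trial_duration))
        t_cursor += trial_duration
    track = PositionTrack(
        times=np.concatenate([tr.times for tr in tracks]),
        x=np.concatenate([tr.x for tr in tracks]),
        y=np.concatenate([tr.y for tr in tracks]),
        valid=np.concatenate([tr.valid for tr in tracks]),
    )

    chan, ref, gt = gen_lfp(track, rng, duration=t_cursor, ripple_rate=ripple_rate, ripple_snr=ripple_snr)
    gt.seed = seed

    # analysis-side constructs needed to drive the generator itself
    from .oscillations import detect_theta_epochs, theta_phase_series

    cfg = OscillationConfig()
    theta_epochs = detect_theta_epochs(chan.samples, chan.sample_rate, cfg)
    phase_series = theta_phase_series(chan.samples, chan.sample_rate, theta_epochs, cfg)
    swr_intervals = np.column_stack(
        [gt.ripple_times - 3 * gt.ripple_duration_sd, gt.ripple_times + 3 * gt.ripple_duration_sd]
    ) if gt.ripple_times.size else np.empty((0, 2))

    maze = ZigzagMaze()
    from .spatial import linearize_zigzag

    lin, _ = maze.project(track.x, track.y)
    run_dir = np.zeros(track.times.size, dtype=int)
    zig_intervals = [t.interval for t in trials if t.label == "zigzag"]
    for a, b in zig_intervals:
        m = (track.times >= a) & (track.times < b)
        sub = PositionTrack(times=track.times[m], x=track.x[m], y=track.y[m], valid=track.valid[m])
        _, d, _ = linearize_zigzag(sub, maze)
        run_dir[m] = d
    open_intervals = [t.interval for t in trials if t.label == "open_field"]

    units: list[Unit] = []
    feats, labels = gen_unit_features(n_pyr, n_int, rng)
    for i in range(n_pyr):
        uid = f"p{i:02d}"
        tuning = PlaceCellTuning(
            peak_rate=rng.uniform(8.0, 15.0),
            field_center=(rng.uniform(10, 60), rng.uniform(10, 60)),
            field_sd=rng.uniform(5.0, 7.0),
            theta_kappa=1.5,
            theta_phase0=rng.uniform(0, 360),
            precession_slope=-1.0,
            swr_gain=rng.uniform(5.0, 12.0),
            linear_center=rng.uniform(40.0, maze.total_length - 40.0),
            linear_sd=rng.uniform(7.0, 10.0),
            direction=int(rng.choice([-1, 1])),
        )
        spikes = []
        for a, b in open_intervals:
            spikes.append(
                gen_place_cell(track, phase_series, tuning, rng, t_range=(a, b), swr_intervals=swr_intervals)
            )
        for a, b in zig_intervals:
            spikes.append(
                gen_place_cell(
                    track, phase_series, tuning, rng, t_range=(a, b),
                    swr_intervals=swr_intervals, linear=lin, lin_direction=run_dir,
                )
            )
        for tr in trials:
            if tr.label == "rest":
                # baseline + SWR-gain firing only
                rest_tuning = PlaceCellTuning(
                    peak_rate=0.0, field_center=(0, 0), field_sd=1.0,
                    baseline_rate=tuning.baseline_rate, theta_kappa=0.0,
                    swr_gain=tuning.swr_gain,
                )
                spikes.append(
                    gen_place_cell(track, phase_series, rest_tuning, rng,
                                   t_range=tr.interval, swr_intervals=swr_intervals)
                )
        st = np.sort(np.concatenate(spikes))
        st = st[np.concatenate(([True], np.diff(st) > 1e-4))]  # 0.1 ms refractoriness
        wf, wf_rate = gen_waveform(feats[i, 2], rng)
        units.append(Unit(uid, f"t{i % 4}", st, mean_waveform=wf, waveform_rate=wf_rate))
        gt.place_tuning[uid] = tuning
        gt.labels[uid] = "pyramidal"
    for j in range(n_int):
        uid = f"i{j:02d}"
        k = n_pyr + j
        tuning_i = InterneuronTuning(
            baseline_rate=float(10 ** feats[k, 0]),
            theta_kappa=rng.uniform(0.4, 0.8),
            theta_phase0=rng.uniform(0, 360),
            ripple_kappa=1.0,
            swr_gain=rng.uniform(1.5, 3.0),
        )
        st = gen_interneuron(phase_series, tuning_i, rng, (0.0, t_cursor), swr_intervals=swr_intervals)
        st = st[np.concatenate(([True], np.diff(st) > 1e-4))]
        wf, wf_rate = gen_waveform(feats[k, 2], rng)
        units.append(Unit(uid, f"t{4 + j % 2}", st, mean_waveform=wf, waveform_rate=wf_rate))
        gt.interneuron_tuning[uid] = tuning_i
        gt.labels[uid] = "interneuron"

    session = RecordingSession(
        session_id=f"synth-{seed}", lfp=[chan] + ([ref] if ref else []),
        units=units, track=track, trials=trials,
    )
    return session, gt
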
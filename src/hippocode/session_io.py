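"""Recording-session data model, fixture I/O, and kinematic preprocessing.

A :class:`RecordingSession` binds together the local field potential (LFP)
channels, single-unit spike trains, the position track and the trial
structure of one recording session.  Times are seconds (float64) from
session start.  Trial epochs and all other intervals are half-open
``[start, end)`` so that adjacent epochs never double-count a sample.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LfpSignal",
    "Unit",
    "PositionTrack",
    "SpeedSeries",
    "TrialEpoch",
    "RecordingSession",
    "ValidationError",
    "read_session",
    "write_session",
    "validate_session",
    "compute_speed",
    "restrict",
    "restrict_track",
]


class ValidationError(ValueError):
    """A session or fixture violated a structural invariant."""


@dataclass
class LfpSignal:
    """One LFP channel: regularly sampled voltage, arbitrary units."""

    channel_id: str
    sample_rate: float
    samples: np.ndarray
    in_pyramidal_layer: bool = True
    is_reference: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError(f"LfpSignal {self.channel_id}: sample_rate must be > 0")
        if self.samples.size == 0:
            raise ValidationError(f"LfpSignal {self.channel_id}: empty signal")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class Unit:
    """A curated single unit: sorted spike times plus its mean waveform."""

    unit_id: str
    tetrode_id: str
    spike_times: np.ndarray
    mean_waveform: np.ndarray | None = None
    waveform_rate: float | None = None
    cluster_features: np.ndarray | None = None  # (n_spikes, n_features), optional

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValidationError(f"Unit {self.unit_id}: spike_times not strictly sorted")
        if self.mean_waveform is not None:
            self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class PositionTrack:
    """Head position at the camera frame rate (nominally 25 Hz), in cm."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.times.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValidationError("PositionTrack: field lengths differ")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("PositionTrack: times not strictly increasing")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class SpeedSeries:
    """Instantaneous running speed (cm/s) on the position-track clock."""

    times: np.ndarray
    speed: np.ndarray
    valid: np.ndarray


@dataclass
class TrialEpoch:
    label: str  # rest | open_field | zigzag
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.label not in ("rest", "open_field", "zigzag"):
            raise ValidationError(f"unknown trial label {self.label!r}")
        if self.end <= self.start:
            raise ValidationError("TrialEpoch: end <= start")

    @property
    def interval(self) -> tuple[float, float]:
        return (self.start, self.end)


@dataclass
class RecordingSession:
    session_id: str
    lfp: list[LfpSignal]
    units: list[Unit]
    track: PositionTrack
    trials: list[TrialEpoch] = field(default_factory=list)

    def trial_intervals(self, label: str | None = None) -> list[tuple[float, float]]:
        return [t.interval for t in self.trials if label is None or t.label == label]

    def get_lfp(self, channel_id: str) -> LfpSignal:
        for ch in self.lfp:
            if ch.channel_id == channel_id:
                return ch
        raise KeyError(channel_id)

    @property
    def pyramidal_layer_channels(self) -> list[LfpSignal]:
        return [c for c in self.lfp if c.in_pyramidal_layer and not c.is_reference]

    @property
    def reference_channel(self) -> LfpSignal | None:
        refs = [c for c in self.lfp if c.is_reference]
        return refs[0] if refs else None


def validate_session(session: RecordingSession, pad: float = 1.0) -> list[str]:
    """Check the structural invariants of a session; return warning strings.

    Hard violations (overlapping or unordered trials, >1 reference channel)
    raise :class:`ValidationError`; soft issues (spikes or position samples
    outside the padded trial union) are returned as warnings.
    """
    warnings: list[str] = []
    trials = session.trials
    for a, b in zip(trials, trials[1:]):
        if b.start < a.end:
            raise ValidationError("trial epochs overlap or are unordered")
    n_ref = sum(c.is_reference for c in session.lfp)
    if n_ref > 1:
        raise ValidationError("more than one reference channel")
    if trials:
        lo = trials[0].start - pad
        hi = trials[-1].end + pad
        for u in session.units:
            if u.n_spikes and (u.spike_times[0] < lo or u.spike_times[-1] > hi):
                warnings.append(f"unit {u.unit_id}: spikes outside trial union (+/-{pad}s)")
        t = session.track.times
        if t.size and (t[0] < lo or t[-1] > hi):
            warnings.append("track: samples outside trial union")
    return warnings


# ---------------------------------------------------------------------------
# Fixture I/O.  One directory per session:
#   session.yaml            ids, rates, trial table, channel/unit metadata
#   lfp_<channel>.bin       little-endian float32
#   units.csv               unit_id, tetrode_id, waveform_rate
#   spikes_<unit>.csv       single column "time" (s)
#   waveform_<unit>.csv     single column "voltage"
#   features_<unit>.csv     optional per-spike feature vectors
#   track.csv               time,x,y,valid
# ---------------------------------------------------------------------------


def write_session(session: RecordingSession, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "lfp": [
            {
                "channel_id": c.channel_id,
                "sample_rate": float(c.sample_rate),
                "in_pyramidal_layer": bool(c.in_pyramidal_layer),
                "is_reference": bool(c.is_reference),
                "file": f"lfp_{c.channel_id}.bin",
            }
            for c in session.lfp
        ],
        "trials": [
            {"label": t.label, "start": float(t.start), "end": float(t.end)}
            for t in session.trials
        ],
    }
    with open(os.path.join(path, "session.yaml"), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    for c in session.lfp:
        c.samples.astype("<f4").tofile(os.path.join(path, f"lfp_{c.channel_id}.bin"))
    rows = [
        {
            "unit_id": u.unit_id,
            "tetrode_id": u.tetrode_id,
            "waveform_rate": u.waveform_rate if u.waveform_rate is not None else "",
        }
        for u in session.units
    ]
    pd.DataFrame(rows, columns=["unit_id", "tetrode_id", "waveform_rate"]).to_csv(
        os.path.join(path, "units.csv"), index=False, float_format="%.17g"
    )
    for u in session.units:
        pd.DataFrame({"time": u.spike_times}).to_csv(
            os.path.join(path, f"spikes_{u.unit_id}.csv"), index=False, float_format="%.17g"
        )
        if u.mean_waveform is not None:
            pd.DataFrame({"voltage": u.mean_waveform}).to_csv(
                os.path.join(path, f"waveform_{u.unit_id}.csv"), index=False, float_format="%.17g"
            )
        if u.cluster_features is not None:
            pd.DataFrame(u.cluster_features).to_csv(
                os.path.join(path, f"features_{u.unit_id}.csv"), index=False, float_format="%.17g"
            )
    pd.DataFrame(
        {
            "time": session.track.times,
            "x": session.track.x,
            "y": session.track.y,
            "valid": session.track.valid.astype(int),
        }
    ).to_csv(os.path.join(path, "track.csv"), index=False, float_format="%.17g")


def read_session(path: str) -> RecordingSession:
    yml = os.path.join(path, "session.yaml")
    if not os.path.exists(yml):
        raise ValidationError(f"{yml}: missing session.yaml")
    with open(yml) as fh:
        meta = yaml.safe_load(fh)
    lfp = []
    for c in meta.get("lfp", []):
        binpath = os.path.join(path, c["file"])
        if not os.path.exists(binpath):
            raise ValidationError(f"{binpath}: missing LFP file")
        samples = np.fromfile(binpath, dtype="<f4").astype(float)
        lfp.append(
            LfpSignal(
                channel_id=c["channel_id"],
                sample_rate=float(c["sample_rate"]),
                samples=samples,
                in_pyramidal_layer=bool(c.get("in_pyramidal_layer", True)),
                is_reference=bool(c.get("is_reference", False)),
            )
        )
    track_path = os.path.join(path, "track.csv")
    if not os.path.exists(track_path):
        raise ValidationError("track: missing track.csv")
    tdf = pd.read_csv(track_path, float_precision="round_trip")
    track = PositionTrack(
        times=tdf["time"].to_numpy(),
        x=tdf["x"].to_numpy(),
        y=tdf["y"].to_numpy(),
        valid=tdf["valid"].to_numpy().astype(bool),
    )
    units = []
    units_path = os.path.join(path, "units.csv")
    if os.path.exists(units_path):
        udf = pd.read_csv(units_path)
        for _, row in udf.iterrows():
            uid = str(row["unit_id"])
            spikes = pd.read_csv(os.path.join(path, f"spikes_{uid}.csv"), float_precision="round_trip")["time"].to_numpy()
            wf_path = os.path.join(path, f"waveform_{uid}.csv")
            waveform = (
                pd.read_csv(wf_path, float_precision="round_trip")["voltage"].to_numpy() if os.path.exists(wf_path) else None
            )
            feat_path = os.path.join(path, f"features_{uid}.csv")
            features = pd.read_csv(feat_path, float_precision="round_trip").to_numpy() if os.path.exists(feat_path) else None
            wf_rate = row.get("waveform_rate")
            units.append(
                Unit(
                    unit_id=uid,
                    tetrode_id=str(row["tetrode_id"]),
                    spike_times=spikes,
                    mean_waveform=waveform,
                    waveform_rate=float(wf_rate) if pd.notna(wf_rate) and wf_rate != "" else None,
                    cluster_features=features,
                )
            )
    trials = [TrialEpoch(t["label"], float(t["start"]), float(t["end"])) for t in meta.get("trials", [])]
    session = RecordingSession(
        session_id=str(meta["session_id"]), lfp=lfp, units=units, track=track, trials=trials
    )
    validate_session(session)
    return session


# ---------------------------------------------------------------------------
# Kinematics
# ---------------------------------------------------------------------------


def _interpolate_short_gaps(track: PositionTrack, max_gap: float = 0.4) -> PositionTrack:
    """Linearly interpolate tracking dropouts no longer than ``max_gap`` s."""
    valid = track.valid.copy()
    x = track.x.copy()
    y = track.y.copy()
    t = track.times
    if valid.all() or not valid.any():
        return PositionTrack(t, x, y, valid)
    idx = np.flatnonzero(valid)
    bad_runs = np.ma.clump_masked(np.ma.masked_where(~valid, valid))
    for run in bad_runs:
        i0, i1 = run.start, run.stop  # invalid samples [i0, i1)
        if i0 == 0 or i1 == t.size:
            continue  # leading/trailing dropouts are not bridged
        if t[i1] - t[i0 - 1] <= max_gap:
            seg = slice(i0, i1)
            x[seg] = np.interp(t[seg], [t[i0 - 1], t[i1]], [x[i0 - 1], x[i1]])
            y[seg] = np.interp(t[seg], [t[i0 - 1], t[i1]], [y[i0 - 1], y[i1]])
            valid[seg] = True
    del idx
    return PositionTrack(t, x, y, valid)


def compute_speed(track: PositionTrack, smoothing_window: float = 0.2) -> SpeedSeries:
    """Running speed via central differences of boxcar-smoothed coordinates.

    Coordinates are boxcar-smoothed over ``smoothing_window`` seconds (to
    suppress camera jitter) before differentiating.  Dropout gaps up to
    0.4 s are bridged by linear interpolation; longer gaps stay invalid and
    propagate to the speed samples that straddle them.
    """
    track = _interpolate_short_gaps(track)
    t, x, y, valid = track.times, track.x, track.y, track.valid
    if int(valid.sum()) < 2:
        raise ValidationError("compute_speed: need >= 2 valid samples")
    dt = float(np.median(np.diff(t)))
    half = max(int(round(smoothing_window / dt / 2)), 0)
    win = 2 * half + 1
    if win > 1:
        kernel = np.ones(win) / win
        xs = np.convolve(np.pad(x, half, mode="edge"), kernel, mode="valid")
        ys = np.convolve(np.pad(y, half, mode="edge"), kernel, mode="valid")
    else:
        xs, ys = x, y
    n = t.size
    speed = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    if n >= 3:
        dx = xs[2:] - xs[:-2]
        dy = ys[2:] - ys[:-2]
        dtt = t[2:] - t[:-2]
        speed[1:-1] = np.hypot(dx, dy) / dtt
        ok[1:-1] = valid[:-2] & valid[1:-1] & valid[2:]
    # endpoints: one-sided difference
    speed[0] = np.hypot(xs[1] - xs[0], ys[1] - ys[0]) / (t[1] - t[0])
    speed[-1] = np.hypot(xs[-1] - xs[-2], ys[-1] - ys[-2]) / (t[-1] - t[-2])
    ok[0] = valid[0] & valid[1]
    ok[-1] = valid[-1] & valid[-2]
    speed[~ok] = np.nan
    return SpeedSeries(times=t, speed=speed, valid=ok)


def restrict(times: np.ndarray, epochs: list[tuple[float, float]]) -> np.ndarray:
    """Keep the time points that fall inside any half-open epoch [start, end)."""
    times = np.asarray(times, dtype=float)
    if not epochs:
        return times[:0]
    epochs = sorted((float(a), float(b)) for a, b in epochs)
    for (a0, b0), (a1, _b1) in zip(epochs, epochs[1:]):
        if a1 < b0:
            raise ValidationError("restrict: overlapping epochs")
    mask = np.zeros(times.size, dtype=bool)
    for a, b in epochs:
        mask |= (times >= a) & (times < b)
    return times[mask]


def restrict_mask(times: np.ndarray, epochs: list[tuple[float, float]]) -> np.ndarray:
    """Boolean membership of each time point in the half-open epoch union."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.size, dtype=bool)
    for a, b in epochs:
        mask |= (times >= a) & (times < b)
    return mask


def restrict_track(track: PositionTrack, epochs: list[tuple[float, float]]) -> PositionTrack:
    mask = restrict_mask(track.times, epochs)
    return PositionTrack(track.times[mask], track.x[mask], track.y[mask], track.valid[mask])
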
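"""LFP filtering, sharp wave/ripple detection, spectra, and phase series.

Sharp wave/ripples (SWRs) are detected as excursions of ripple-band
(125-250 Hz) RMS power: the power is computed in 20 ms windows stepped by
10 ms, any window exceeding mean + 7 SD seeds an epoch, and the epoch
extends in both directions until the power drops below mean + 2.5 SD.
A non-pyramidal-layer reference channel vetoes candidate epochs that
coincide with its own ripple-band power excursions (muscle artifacts).

Theta epochs are 500 ms windows whose theta (6-10 Hz) to delta (2-4 Hz)
RMS ratio exceeds 2.  Oscillation phase is anchored to the
positive-to-negative zero-crossings of the band-filtered trace (phase 0
degrees) and interpolated linearly to 360 degrees across each cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .session_io import LfpSignal

__all__ = [
    "OscillationConfig",
    "PowerSeries",
    "SwrEpoch",
    "TimeFrequencyMap",
    "PhaseSeries",
    "bandpass",
    "windowed_rms",
    "detect_swr",
    "characterize_swr",
    "morlet_tf",
    "mean_swr_tf",
    "multitaper_psd",
    "detect_theta_epochs",
    "theta_phase_series",
    "ripple_phase_series",
    "descending_zero_crossings",
]


@dataclass
class OscillationConfig:
    """Detection parameters; defaults follow the analysis conventions above."""

    ripple_band: tuple[float, float] = (125.0, 250.0)
    rms_window: float = 0.020
    rms_step: float = 0.010
    swr_enter_sd: float = 7.0
    swr_exit_sd: float = 2.5
    ref_reject_sd: float = 7.0
    ref_reject_pad: float = 0.020  # s around seed windows checked on the reference
    min_swr_duration: float = 0.020
    swr_merge_gap: float = 0.010
    theta_band: tuple[float, float] = (6.0, 10.0)
    delta_band: tuple[float, float] = (2.0, 4.0)
    theta_ratio_window: float = 0.5
    theta_ratio_threshold: float = 2.0
    phase_filter_band: tuple[float, float] = (5.0, 14.0)
    filter_order: int = 4
    multitaper_nw: float = 3.0
    multitaper_k: int = 5
    # per-epoch peak-frequency spectra use one low-order taper: a brief
    # (tens of ms) epoch with K=5/NW=3 has a +-NW/T plateau that drowns the
    # carrier; one concentrated taper keeps the spectral peak on it
    peak_freq_nw: float = 1.5
    peak_freq_k: int = 1
    wavelet_freqs: tuple[float, float, float] = (90.0, 300.0, 2.0)  # lo, hi, step
    swr_tf_half_width: float = 0.125
    speed_bins: tuple[float, ...] = (3.0, 8.0, 13.0, 18.0, 23.0, np.inf)

    def __post_init__(self) -> None:
        for lo, hi in (self.ripple_band, self.theta_band, self.delta_band, self.phase_filter_band):
            if lo >= hi:
                raise ValueError("band low must be < band high")
        if self.swr_enter_sd <= self.swr_exit_sd:
            raise ValueError("enter threshold must exceed exit threshold")


@dataclass
class PowerSeries:
    """Windowed RMS power with the baseline statistics used for thresholds."""

    window_centers: np.ndarray
    rms: np.ndarray
    mean: float
    sd: float
    window: float
    step: float


@dataclass
class SwrEpoch:
    start: float
    end: float
    peak_power_time: float | None = None
    cycles: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_frequency: float | None = None
    amplitude: float | None = None
    flagged: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class TimeFrequencyMap:
    times: np.ndarray
    frequencies: np.ndarray
    magnitude: np.ndarray  # (n_freq, n_time), >= 0


@dataclass
class PhaseSeries:
    """Oscillation phase, valid only inside detected epochs.

    ``segments`` holds, per valid epoch, the zero-crossing times that anchor
    the interpolation; spike phases are interpolated from these directly.
    """

    times: np.ndarray
    phase_deg: np.ndarray
    valid: np.ndarray
    segments: list[np.ndarray] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Filtering and power
# ---------------------------------------------------------------------------


def bandpass(samples: np.ndarray, fs: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band high {hi} Hz >= Nyquist {fs / 2} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def windowed_rms(
    samples: np.ndarray,
    fs: float,
    window: float,
    step: float,
    t0: float = 0.0,
    baseline_epochs: list[tuple[float, float]] | None = None,
) -> PowerSeries:
    """RMS power in sliding windows of ``window`` s every ``step`` s.

    Window k covers ``[c_k - window/2, c_k + window/2)`` with the first
    center at ``t0 + window/2``.  ``mean``/``sd`` of the series are computed
    over all windows, or over the windows whose centers fall inside
    ``baseline_epochs`` when given (e.g. rest trials only).
    """
    if window < step:
        raise ValueError("window must be >= step")
    x = np.asarray(samples, dtype=float)
    wlen = int(round(window * fs))
    slen = int(round(step * fs))
    if x.size < wlen:
        raise ValueError("signal shorter than one window")
    n_win = (x.size - wlen) // slen + 1
    starts = np.arange(n_win) * slen
    sq = np.concatenate(([0.0], np.cumsum(x * x)))
    rms = np.sqrt((sq[starts + wlen] - sq[starts]) / wlen)
    centers = t0 + (starts + wlen / 2) / fs
    if baseline_epochs is not None:
        mask = np.zeros(n_win, dtype=bool)
        for a, b in baseline_epochs:
            mask |= (centers >= a) & (centers < b)
        base = rms[mask] if mask.any() else rms
    else:
        base = rms
    return PowerSeries(
        window_centers=centers,
        rms=rms,
        mean=float(base.mean()),
        sd=float(base.std()),
        window=window,
        step=step,
    )


# ---------------------------------------------------------------------------
# SWR detection
# ---------------------------------------------------------------------------


def detect_swr(
    power: PowerSeries,
    ref_power: PowerSeries | None = None,
    cfg: OscillationConfig | None = None,
    two_pass: bool = True,
) -> list[SwrEpoch]:
    """Detect SWR epoch boundaries from a ripple-band power series.

    Each maximal run seeded by a window above ``mean + enter_sd*sd`` and
    extended both ways through windows at or above ``mean + exit_sd*sd``
    becomes one epoch spanning [first window start, last window end].
    Epochs whose seed windows coincide (within ``ref_reject_pad``) with
    reference-channel excursions above its own mean + ``ref_reject_sd``*sd
    are discarded; overlapping or near-adjacent epochs are merged.

    With ``two_pass`` (default) the baseline mean/SD is re-estimated after
    excluding first-pass detections, so genuine ripple windows do not
    inflate the SD of the supposedly ripple-free baseline.
    """
    cfg = cfg or OscillationConfig()
    if power.sd == 0:
        return []
    if two_pass:
        first = detect_swr(power, ref_power=None, cfg=cfg, two_pass=False)
        if first:
            keep_mask = np.ones(power.rms.size, dtype=bool)
            for ep in first:
                keep_mask &= ~(
                    (power.window_centers >= ep.start - 2 * cfg.rms_window)
                    & (power.window_centers <= ep.end + 2 * cfg.rms_window)
                )
            if keep_mask.any():
                power = PowerSeries(
                    window_centers=power.window_centers,
                    rms=power.rms,
                    mean=float(power.rms[keep_mask].mean()),
                    sd=float(power.rms[keep_mask].std()),
                    window=power.window,
                    step=power.step,
                )
        return detect_swr(power, ref_power=ref_power, cfg=cfg, two_pass=False)
    z = (power.rms - power.mean) / power.sd
    seed = z > cfg.swr_enter_sd
    keep = z >= cfg.swr_exit_sd
    if not seed.any():
        return []

    ref_bad_times: np.ndarray | None = None
    if ref_power is not None and ref_power.sd > 0:
        zr = (ref_power.rms - ref_power.mean) / ref_power.sd
        ref_bad_times = ref_power.window_centers[zr > cfg.ref_reject_sd]

    half = power.window / 2
    epochs: list[tuple[float, float]] = []
    n = z.size
    # contiguous runs of keep-windows that contain at least one seed window
    run_start = None
    for i in range(n + 1):
        inside = i < n and keep[i]
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            i0, i1 = run_start, i - 1
            run_start = None
            seeds = np.flatnonzero(seed[i0 : i1 + 1]) + i0
            if seeds.size == 0:
                continue
            if ref_bad_times is not None and ref_bad_times.size:
                seed_times = power.window_centers[seeds]
                d = np.min(
                    np.abs(seed_times[:, None] - ref_bad_times[None, :]), axis=1
                )
                if np.any(d <= cfg.ref_reject_pad):
                    continue
            epochs.append(
                (power.window_centers[i0] - half, power.window_centers[i1] + half)
            )

    # merge overlapping / near-adjacent epochs, then apply minimum duration
    merged: list[list[float]] = []
    for a, b in epochs:
        if merged and a - merged[-1][1] <= cfg.swr_merge_gap:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [
        SwrEpoch(start=a, end=b)
        for a, b in merged
        if b - a >= cfg.min_swr_duration
    ]


def descending_zero_crossings(x: np.ndarray, fs: float, t0: float = 0.0) -> np.ndarray:
    """Times of positive-to-negative zero-crossings, linearly interpolated."""
    x = np.asarray(x, dtype=float)
    idx = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0))
    if idx.size == 0:
        return np.empty(0)
    frac = x[idx] / (x[idx] - x[idx + 1])
    return t0 + (idx + frac) / fs


def characterize_swr(
    epoch: SwrEpoch,
    filtered: np.ndarray,
    fs: float,
    power: PowerSeries,
    cfg: OscillationConfig | None = None,
    t0: float = 0.0,
) -> SwrEpoch:
    """Fill in peak-power time, ripple cycles, amplitude and peak frequency.

    Amplitude is half the peak-to-trough excursion of the band-filtered
    trace within one ripple cycle of the peak-power window; peak frequency
    is the location of the ripple-band maximum of the epoch's multitaper
    spectrum.
    """
    cfg = cfg or OscillationConfig()
    in_ep = (power.window_centers >= epoch.start) & (power.window_centers <= epoch.end)
    if not in_ep.any():
        return replace(epoch, flagged=True)
    idx = np.flatnonzero(in_ep)
    peak_i = idx[np.argmax(power.rms[idx])]
    peak_time = float(power.window_centers[peak_i])
    # clamp strictly inside the epoch
    peak_time = min(max(peak_time, epoch.start + 1e-9), epoch.end - 1e-9)

    i0 = max(int(round((epoch.start - t0) * fs)), 0)
    i1 = min(int(round((epoch.end - t0) * fs)), filtered.size)
    seg = filtered[i0:i1]
    cycles = descending_zero_crossings(seg, fs, t0=t0 + i0 / fs)
    if cycles.size == 0:
        return replace(epoch, peak_power_time=peak_time, flagged=True)

    # amplitude: half peak-to-trough within one cycle length of the peak
    period = float(np.median(np.diff(cycles))) if cycles.size > 1 else 1.0 / 180.0
    a0 = max(int(round((peak_time - period - t0) * fs)), 0)
    a1 = min(int(round((peak_time + period - t0) * fs)), filtered.size)
    win = filtered[a0:a1]
    amplitude = float(win.max() - win.min()) / 2 if win.size else None

    # peak frequency from the epoch's multitaper ripple-band spectrum;
    # zero-padded FFT for a fine enough frequency grid on short epochs
    freqs, psd = multitaper_psd(
        [seg], fs, nw=cfg.peak_freq_nw, k=cfg.peak_freq_k, nfft=max(1024, seg.size)
    )
    band = (freqs >= cfg.ripple_band[0]) & (freqs <= cfg.ripple_band[1])
    peak_frequency = float(freqs[band][np.argmax(psd[band])]) if band.any() else None

    return replace(
        epoch,
        peak_power_time=peak_time,
        cycles=cycles,
        amplitude=amplitude,
        peak_frequency=peak_frequency,
    )


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def _morlet_wavelet(f: float, fs: float) -> np.ndarray:
    """Complex Morlet wavelet, temporal SD one period, unit total energy."""
    sd = 1.0 / f
    half = int(np.ceil(5 * sd * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t**2) / (2 * sd**2)) * np.exp(2j * np.pi * f * t)
    energy = np.sum(np.abs(w) ** 2) / fs
    return w / np.sqrt(energy)


def morlet_tf(samples: np.ndarray, fs: float, frequencies: np.ndarray, t0: float = 0.0) -> TimeFrequencyMap:
    """Morlet-wavelet time-frequency magnitude map.

    Every wavelet has a temporal SD of one period and is normalized to the
    same (unit) total energy, so the expected energy of each frequency row
    is frequency-independent for white-noise input.
    """
    frequencies = np.asarray(frequencies, dtype=float)
    if frequencies.size == 0:
        raise ValueError("empty frequency list")
    if frequencies.max() >= fs / 2:
        raise ValueError("max frequency >= Nyquist")
    x = np.asarray(samples, dtype=float)
    mag = np.empty((frequencies.size, x.size))
    for i, f in enumerate(frequencies):
        w = _morlet_wavelet(f, fs)
        mag[i] = np.abs(sps.fftconvolve(x, w, mode="same"))
    times = t0 + np.arange(x.size) / fs
    return TimeFrequencyMap(times=times, frequencies=frequencies, magnitude=mag)


def mean_swr_tf(
    samples: np.ndarray,
    fs: float,
    epochs: list[SwrEpoch],
    half_width: float = 0.125,
    frequencies: np.ndarray | None = None,
    cfg: OscillationConfig | None = None,
    t0: float = 0.0,
) -> TimeFrequencyMap:
    """Average the raw-signal wavelet map around each SWR's peak power."""
    cfg = cfg or OscillationConfig()
    if frequencies is None:
        lo, hi, step = cfg.wavelet_freqs
        frequencies = np.arange(lo, hi + step / 2, step)
    if not epochs:
        raise ValueError("mean_swr_tf: need >= 1 epoch")
    half_n = int(round(half_width * fs))
    rel_times = np.arange(-half_n, half_n + 1) / fs
    acc = np.zeros((len(frequencies), rel_times.size))
    n_used = 0
    x = np.asarray(samples, dtype=float)
    for ep in epochs:
        if ep.peak_power_time is None:
            continue
        c = int(round((ep.peak_power_time - t0) * fs))
        lo_i, hi_i = c - half_n, c + half_n + 1
        pad = 5 * int(np.ceil(fs / min(frequencies)))  # wavelet support margin
        if lo_i - pad < 0 or hi_i + pad > x.size:
            warnings.warn("mean_swr_tf: epoch window exceeds signal, skipped")
            continue
        tf = morlet_tf(x[lo_i - pad : hi_i + pad], fs, frequencies)
        acc += tf.magnitude[:, pad : pad + rel_times.size]
        n_used += 1
    if n_used == 0:
        raise ValueError("mean_swr_tf: no usable epoch")
    return TimeFrequencyMap(times=rel_times, frequencies=np.asarray(frequencies, float), magnitude=acc / n_used)


def multitaper_psd(
    segments: list[np.ndarray],
    fs: float,
    nw: float = 3.0,
    k: int = 5,
    nfft: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper (DPSS) one-sided PSD averaged over tapers and segments.

    Shorter segments are zero-padded to the longest; ``nfft`` zero-pads the
    tapered products further to refine the frequency grid.  The density
    satisfies Parseval: ``sum(psd) * df`` approximates the signal variance.
    """
    if not segments:
        raise ValueError("multitaper_psd: empty segment list")
    segs = [np.asarray(s, dtype=float) for s in segments]
    n = max(s.size for s in segs)
    nfft = max(nfft or n, n)
    tapers = sps.windows.dpss(n, nw, Kmax=k)  # rows are unit-energy tapers
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    acc = np.zeros(freqs.size)
    for s in segs:
        if s.size < n:
            s = np.pad(s, (0, n - s.size))
        spec = np.abs(np.fft.rfft(tapers * s[None, :], n=nfft, axis=1)) ** 2
        acc += spec.mean(axis=0)
    psd = acc / len(segs) / fs
    # one-sided: double interior bins
    psd[1:] *= 2.0
    if nfft % 2 == 0:
        psd[-1] /= 2.0
    return freqs, psd


# ---------------------------------------------------------------------------
# Theta
# ---------------------------------------------------------------------------


def detect_theta_epochs(
    samples: np.ndarray,
    fs: float,
    cfg: OscillationConfig | None = None,
    t0: float = 0.0,
) -> list[tuple[float, float]]:
    """Intervals where the theta/delta RMS ratio exceeds the threshold.

    The ratio is evaluated in consecutive non-overlapping windows
    (default 500 ms); contiguous supra-threshold windows are merged.
    """
    cfg = cfg or OscillationConfig()
    x = np.asarray(samples, dtype=float)
    wlen = int(round(cfg.theta_ratio_window * fs))
    if x.size < wlen:
        raise ValueError("signal shorter than one theta window")
    theta = bandpass(x, fs, cfg.theta_band, cfg.filter_order)
    delta = bandpass(x, fs, cfg.delta_band, cfg.filter_order)
    n_win = x.size // wlen
    epochs: list[list[float]] = []
    for kk in range(n_win):
        seg = slice(kk * wlen, (kk + 1) * wlen)
        rms_t = np.sqrt(np.mean(theta[seg] ** 2))
        rms_d = np.sqrt(np.mean(delta[seg] ** 2))
        if rms_d == 0 or rms_t / rms_d > cfg.theta_ratio_threshold:
            a = t0 + kk * wlen / fs
            b = t0 + (kk + 1) * wlen / fs
            if epochs and abs(a - epochs[-1][1]) < 1e-9:
                epochs[-1][1] = b
            else:
                epochs.append([a, b])
    return [(a, b) for a, b in epochs]


def _phase_from_crossings(
    times: np.ndarray,
    epochs: list[tuple[float, float]],
    crossings: np.ndarray,
) -> PhaseSeries:
    """Linear 0-360 degree interpolation between consecutive zero-crossings."""
    phase = np.full(times.size, np.nan)
    valid = np.zeros(times.size, dtype=bool)
    segments: list[np.ndarray] = []
    for a, b in epochs:
        cr = crossings[(crossings >= a) & (crossings < b)]
        if cr.size < 2:
            continue
        segments.append(cr)
        in_seg = (times >= cr[0]) & (times < cr[-1])
        idx = np.flatnonzero(in_seg)
        if idx.size == 0:
            continue
        pos = np.searchsorted(cr, times[idx], side="right") - 1
        frac = (times[idx] - cr[pos]) / (cr[pos + 1] - cr[pos])
        phase[idx] = 360.0 * frac
        valid[idx] = True
    return PhaseSeries(times=times, phase_deg=phase, valid=valid, segments=segments)


def theta_phase_series(
    samples: np.ndarray,
    fs: float,
    theta_epochs: list[tuple[float, float]],
    cfg: OscillationConfig | None = None,
    t0: float = 0.0,
) -> PhaseSeries:
    """Theta phase from the 5-14 Hz filtered trace, 0 deg at descending crossings."""
    cfg = cfg or OscillationConfig()
    filt = bandpass(np.asarray(samples, float), fs, cfg.phase_filter_band, cfg.filter_order)
    crossings = descending_zero_crossings(filt, fs, t0=t0)
    times = t0 + np.arange(len(filt)) / fs
    return _phase_from_crossings(times, theta_epochs, crossings)


def ripple_phase_series(
    filtered: np.ndarray,
    fs: float,
    epochs: list[SwrEpoch],
    t0: float = 0.0,
) -> PhaseSeries:
    """Ripple phase inside SWR epochs, interpolated between ripple cycles."""
    times = t0 + np.arange(len(filtered)) / fs
    intervals = [(ep.start, ep.end) for ep in epochs]
    all_cycles = (
        np.sort(np.concatenate([ep.cycles for ep in epochs if ep.cycles.size]))
        if epochs
        else np.empty(0)
    )
    return _phase_from_crossings(times, intervals, all_cycles)
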
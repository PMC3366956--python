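"""Circular statistics of spike phases and theta/ripple phase coding.

Spike phases are interpolated from a :class:`~hippocode.oscillations.PhaseSeries`
(0 degrees at the positive-to-negative zero-crossing).  Phase locking is
summarized by the mean resultant vector length and circular mean with a
Rayleigh uniformity test; theta phase precession is quantified by a
circular-linear correlation between spike phase and relative position in
the place field, fitted by maximizing the resultant of the phase residuals
over candidate slopes and tested by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oscillations import PhaseSeries, SwrEpoch

__all__ = [
    "PhaseStats",
    "PrecessionFit",
    "SwrSpikeDistribution",
    "SpatioTemporalMap",
    "phases_of_spikes",
    "circ_stats",
    "rayleigh_p",
    "watson_two_sample",
    "firing_probability_by_phase",
    "burst_theta_frequency",
    "swr_spike_distribution",
    "swr_rate_histogram",
    "precession_fit",
    "field_segment_phase_rates",
    "spatiotemporal_map",
]

# Asymptotic critical values for the two-sample Watson U^2 statistic
WATSON_U2_CRIT = {0.05: 0.187, 0.01: 0.268}


@dataclass
class PhaseStats:
    n: int
    mean_phase: float  # degrees in [0, 360)
    vector_length: float  # in [0, 1]
    rayleigh_p: float


@dataclass
class PrecessionFit:
    slope: float  # cycles per field traversal (degrees/360 per unit position)
    offset: float  # degrees
    r: float  # signed circular-linear correlation
    p: float  # permutation p-value
    n: int
    flagged: bool = False


@dataclass
class SwrSpikeDistribution:
    probabilities: np.ndarray  # p(0..k_max spikes per SWR)
    p_more: float  # p(> k_max)
    mean_rate: float  # Hz inside SWRs


@dataclass
class SpatioTemporalMap:
    position_edges: np.ndarray  # relative position in [0, 1]
    phase_edges: np.ndarray  # degrees
    rate: np.ndarray  # (n_pos, n_phase), >= 0


# ---------------------------------------------------------------------------
# Spike phases & circular statistics
# ---------------------------------------------------------------------------


def phases_of_spikes(
    spike_times: np.ndarray, phase_series: PhaseSeries
) -> tuple[np.ndarray, int]:
    """Phase of each spike by linear interpolation between zero-crossings.

    Returns (phases_deg, n_dropped) where dropped spikes fell outside the
    valid segments of the phase series.
    """
    t = np.asarray(spike_times, dtype=float)
    phases = np.full(t.size, np.nan)
    for cr in phase_series.segments:
        inside = (t >= cr[0]) & (t < cr[-1])
        if not inside.any():
            continue
        pos = np.searchsorted(cr, t[inside], side="right") - 1
        frac = (t[inside] - cr[pos]) / (cr[pos + 1] - cr[pos])
        phases[inside] = 360.0 * frac
    ok = ~np.isnan(phases)
    return phases[ok], int((~ok).sum())


def rayleigh_p(n: int, R: float) -> float:
    """Rayleigh uniformity test p-value (standard approximation)."""
    Z = n * R * R
    p = np.exp(-Z) * (1 + (2 * Z - Z * Z) / (4 * n))
    return float(min(1.0, max(0.0, p)))


def circ_stats(phases_deg: np.ndarray) -> PhaseStats:
    """Mean phase, resultant vector length, and Rayleigh p of spike phases."""
    ph = np.deg2rad(np.asarray(phases_deg, dtype=float))
    n = ph.size
    if n == 0:
        raise ValueError("circ_stats: no phases")
    C = np.cos(ph).sum()
    S = np.sin(ph).sum()
    R = float(np.hypot(C, S) / n)
    mean = float(np.rad2deg(np.arctan2(S, C)) % 360.0)
    return PhaseStats(n=n, mean_phase=mean, vector_length=R, rayleigh_p=rayleigh_p(n, R))


def watson_two_sample(phases_a: np.ndarray, phases_b: np.ndarray):
    """Watson's U^2 two-sample test for homogeneity of circular data.

    Returns (U2, significant_at) where significant_at is the smallest of
    the tabulated levels {0.01, 0.05} exceeded, or None.
    """
    a = np.sort(np.asarray(phases_a, dtype=float) % 360.0)
    b = np.sort(np.asarray(phases_b, dtype=float) % 360.0)
    n, m = a.size, b.size
    if n < 8 or m < 8:
        raise ValueError("watson_two_sample: need >= 8 samples per group")
    N = n + m
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    is_a = order < n
    # cumulative empirical fractions at each ordered point
    ca = np.cumsum(is_a) / n
    cb = np.cumsum(~is_a) / m
    d = ca - cb
    U2 = (n * m) / (N**2) * (np.sum(d**2) - np.sum(d) ** 2 / N)
    sig = None
    if U2 > WATSON_U2_CRIT[0.01]:
        sig = 0.01
    elif U2 > WATSON_U2_CRIT[0.05]:
        sig = 0.05
    return float(U2), sig


# ---------------------------------------------------------------------------
# Phase histograms and SWR firing
# ---------------------------------------------------------------------------


def _n_complete_cycles(phase_series: PhaseSeries) -> int:
    return int(sum(max(cr.size - 1, 0) for cr in phase_series.segments))


def firing_probability_by_phase(
    spike_phases: np.ndarray, phase_series: PhaseSeries, bins: int = 12
) -> np.ndarray:
    """Probability of a spike per phase bin per complete oscillation cycle."""
    n_cycles = _n_complete_cycles(phase_series)
    if n_cycles == 0:
        raise ValueError("firing_probability_by_phase: no complete cycles")
    counts, _ = np.histogram(
        np.asarray(spike_phases, float) % 360.0, bins=bins, range=(0.0, 360.0)
    )
    return counts / n_cycles


def burst_theta_frequency(
    spike_times: np.ndarray,
    theta_epochs: list[tuple[float, float]],
    window_ms: float = 200.0,
    bin_ms: float = 2.0,
    search_ms: tuple[float, float] = (70.0, 180.0),
    min_spikes: int = 50,
) -> tuple[float, float, bool]:
    """Intrinsic theta firing frequency from the in-epoch autocorrelation.

    The spike-time autocorrelation (+-window, 2 ms bins) is smoothed with a
    3-bin boxcar; the lag of its maximum within [70, 180] ms gives the burst
    period t* and the frequency 1000/t* Hz.  Returns (freq_hz, t_star_ms,
    low_confidence).
    """
    from .session_io import restrict

    t = restrict(np.asarray(spike_times, float), theta_epochs)
    low_conf = t.size < min_spikes
    if t.size < 2:
        raise ValueError("burst_theta_frequency: too few in-epoch spikes")
    window = window_ms / 1000.0
    lags = []
    hi = np.searchsorted(t, t + window, side="right")
    for i in range(t.size - 1):
        if hi[i] > i + 1:
            lags.append(t[i + 1 : hi[i]] - t[i])
    if not lags:
        raise ValueError("burst_theta_frequency: empty autocorrelation")
    all_lags = np.concatenate(lags) * 1000.0
    n_bins = int(round(window_ms / bin_ms))
    counts, edges = np.histogram(all_lags, bins=n_bins, range=(0.0, window_ms))
    smoothed = np.convolve(counts.astype(float), np.ones(3) / 3, mode="same")
    centers = (edges[:-1] + edges[1:]) / 2
    in_range = (centers >= search_ms[0]) & (centers <= search_ms[1])
    if not in_range.any() or smoothed[in_range].max() == 0:
        raise ValueError("burst_theta_frequency: no peak in search range")
    t_star = float(centers[in_range][np.argmax(smoothed[in_range])])
    return 1000.0 / t_star, t_star, low_conf


def swr_spike_distribution(
    spike_times: np.ndarray, epochs: list[SwrEpoch], k_max: int = 5
) -> SwrSpikeDistribution:
    """Distribution of spikes fired per SWR epoch, plus the in-SWR rate."""
    if not epochs:
        raise ValueError("swr_spike_distribution: no epochs")
    t = np.asarray(spike_times, dtype=float)
    counts = np.array(
        [np.count_nonzero((t >= ep.start) & (t < ep.end)) for ep in epochs]
    )
    probs = np.array([(counts == k).mean() for k in range(k_max + 1)])
    p_more = float((counts > k_max).mean())
    total_dur = sum(ep.duration for ep in epochs)
    return SwrSpikeDistribution(
        probabilities=probs, p_more=p_more, mean_rate=float(counts.sum() / total_dur)
    )


def swr_rate_histogram(
    spike_times: np.ndarray,
    epochs: list[SwrEpoch],
    half_width: float = 0.25,
    bin_width: float = 0.010,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean firing rate around SWR peak power (time 0 = peak power)."""
    if not epochs:
        raise ValueError("swr_rate_histogram: no epochs")
    t = np.asarray(spike_times, dtype=float)
    edges = np.arange(-half_width, half_width + bin_width / 2, bin_width)
    acc = np.zeros(edges.size - 1)
    n_used = 0
    for ep in epochs:
        if ep.peak_power_time is None:
            continue
        rel = t[(t >= ep.peak_power_time - half_width) & (t < ep.peak_power_time + half_width)]
        c, _ = np.histogram(rel - ep.peak_power_time, bins=edges)
        acc += c
        n_used += 1
    if n_used == 0:
        raise ValueError("swr_rate_histogram: no characterized epochs")
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, acc / n_used / bin_width


# ---------------------------------------------------------------------------
# Theta phase precession
# ---------------------------------------------------------------------------


def _resultant_by_slope(
    phases_rad: np.ndarray, x: np.ndarray, slopes: np.ndarray
) -> np.ndarray:
    """Mean resultant length of (theta - 2*pi*a*x) for each candidate slope."""
    # exp(i(theta - 2 pi a x)) = exp(i theta) * exp(-i 2 pi a x)
    E = np.exp(1j * phases_rad)
    W = np.exp(-2j * np.pi * np.outer(slopes, x))
    return np.abs(W @ E) / x.size


def _circ_circ_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Jammalamadaka-SenGupta circular-circular correlation (radians)."""
    sa = np.sin(a - np.angle(np.exp(1j * a).mean()))
    sb = np.sin(b - np.angle(np.exp(1j * b).mean()))
    den = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if den == 0:
        return 0.0
    return float(np.sum(sa * sb) / den)


def precession_fit(
    spike_phases_deg: np.ndarray,
    rel_positions: np.ndarray,
    slope_bound: float = 2.0,
    n_permutations: int = 1000,
    seed: int | None = 0,
) -> PrecessionFit:
    """Circular-linear correlation between spike phase and in-field position.

    The slope (cycles per field traversal) maximizes the mean resultant
    length of the phase residuals over a in [-slope_bound, slope_bound]
    (coarse grid then golden-section refinement).  The signed correlation r
    is the circular-circular correlation between the observed phases and
    the fitted line, with sign matching the slope; p comes from permuting
    positions against phases and recomputing the best resultant.
    """
    ph = np.deg2rad(np.asarray(spike_phases_deg, dtype=float))
    x = np.asarray(rel_positions, dtype=float)
    n = ph.size
    if n < 10:
        raise ValueError("precession_fit: need >= 10 spikes")
    if np.allclose(ph, ph[0]) or np.allclose(x, x[0]):
        return PrecessionFit(slope=0.0, offset=float(np.rad2deg(ph[0]) % 360), r=0.0, p=1.0, n=n, flagged=True)

    # the permutation test compares observed and permuted maxima on the
    # same coarse grid so the null statistic is exchangeable
    coarse = np.arange(-slope_bound, slope_bound + 1e-9, 0.02)
    R_coarse = _resultant_by_slope(ph, x, coarse)
    obs_stat = float(R_coarse.max())
    a0 = float(coarse[np.argmax(R_coarse)])

    # refine the reported slope on a fine local grid
    fine = np.arange(a0 - 0.02, a0 + 0.02 + 1e-9, 1e-3)
    fine = fine[(fine >= -slope_bound) & (fine <= slope_bound)]
    R_fine = _resultant_by_slope(ph, x, fine)
    slope = float(fine[np.argmax(R_fine)])
    resid = ph - 2 * np.pi * slope * x
    offset = float(np.rad2deg(np.angle(np.exp(1j * resid).mean())) % 360.0)
    fitted = 2 * np.pi * slope * x + np.deg2rad(offset)
    rho = _circ_circ_corr(ph, fitted)
    r = float(np.sign(slope) * abs(rho)) if slope != 0 else float(rho)

    rng = np.random.default_rng(seed)
    E = np.exp(1j * ph)
    # columns: permuted exp(i theta); rows of W: slope grid
    perm_idx = np.argsort(rng.random((n, n_permutations)), axis=0)
    P = E[perm_idx]
    W = np.exp(-2j * np.pi * np.outer(coarse, x))
    null_stats = np.max(np.abs(W @ P) / n, axis=0)
    p = float((1 + np.sum(null_stats >= obs_stat)) / (1 + n_permutations))
    return PrecessionFit(slope=slope, offset=offset, r=r, p=p, n=n)


def field_segment_phase_rates(
    spike_phases_deg: np.ndarray,
    spike_rel_positions: np.ndarray,
    occupancy_cycles_per_segment: np.ndarray | None = None,
    cycle_duration_s: float | None = None,
    n_segments: int = 4,
    phase_bins: int = 12,
) -> np.ndarray:
    """Firing rate per (field segment x phase bin).

    The field is split into ``n_segments`` equal lengths on the position
    axis and spikes are assigned by the position at which they occurred.
    When the number of theta cycles spent in each segment is provided the
    counts are normalized to spikes/cycle/bin and, given the mean cycle
    duration, converted to Hz; otherwise raw counts are returned.
    """
    ph = np.asarray(spike_phases_deg, dtype=float) % 360.0
    x = np.clip(np.asarray(spike_rel_positions, dtype=float), 0.0, 1.0 - 1e-12)
    seg = np.minimum((x * n_segments).astype(int), n_segments - 1)
    out = np.zeros((n_segments, phase_bins))
    for s in range(n_segments):
        counts, _ = np.histogram(ph[seg == s], bins=phase_bins, range=(0.0, 360.0))
        out[s] = counts
    if occupancy_cycles_per_segment is not None:
        cyc = np.asarray(occupancy_cycles_per_segment, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(cyc[:, None] > 0, out / cyc[:, None], 0.0)
        if cycle_duration_s is not None:
            out = out / (cycle_duration_s / phase_bins)
    return out


def spatiotemporal_map(
    spike_phases_deg: np.ndarray,
    spike_rel_positions: np.ndarray,
    traversal_occupancy: np.ndarray | None = None,
    pos_bins: int = 20,
    phase_bins: int = 24,
    smooth_sd_bins: float = 1.0,
) -> SpatioTemporalMap:
    """2D spike density over (relative field position, theta phase).

    Normalized by per-position-bin traversal occupancy when provided, then
    smoothed with a small Gaussian (circular in the phase dimension).
    """
    from scipy import ndimage

    ph = np.asarray(spike_phases_deg, dtype=float) % 360.0
    x = np.clip(np.asarray(spike_rel_positions, dtype=float), 0.0, 1.0)
    H, pe, fe = np.histogram2d(
        x, ph, bins=(pos_bins, phase_bins), range=((0.0, 1.0), (0.0, 360.0))
    )
    if traversal_occupancy is not None:
        occ = np.asarray(traversal_occupancy, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            H = np.where(occ[:, None] > 0, H / occ[:, None], 0.0)
    H = ndimage.gaussian_filter1d(H, smooth_sd_bins, axis=1, mode="wrap")
    H = ndimage.gaussian_filter1d(H, smooth_sd_bins, axis=0, mode="nearest")
    return SpatioTemporalMap(position_edges=pe, phase_edges=fe, rate=H)
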
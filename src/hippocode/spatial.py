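"""Occupancy and firing-rate maps, place fields, and spatial selectivity.

The arena is divided into 2x2 cm bins (2 cm bins on the linearized maze).
Only periods with running speed above 3 cm/s enter the maps.  Spike-count
and occupancy maps are smoothed with the same Gaussian kernel (SD 3 cm,
truncated at 3 SD, edge-renormalized so total occupancy is conserved) and
divided to give the firing-rate map.  Place fields are detected by
iterative peak-seeded flood fill; spatial selectivity is quantified by the
Skaggs information score (bits/spike) and sparsity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .session_io import PositionTrack, SpeedSeries

__all__ = [
    "RateMap",
    "PlaceField",
    "SelectivityScores",
    "occupancy_map",
    "rate_map",
    "detect_fields_2d",
    "detect_fields_1d",
    "spatial_information",
    "sparsity",
    "map_stability",
    "ZigzagMaze",
    "linearize_zigzag",
    "MIN_FIELD_PEAK_HZ",
    "FIELD_EXTENT_FRACTION",
    "MIN_FIELD_BINS_2D",
    "MIN_SPIKES_PER_TRIAL",
]

BIN_SIZE = 2.0  # cm
SMOOTH_SD = 3.0  # cm
MIN_SPEED = 3.0  # cm/s
MIN_OCCUPANCY = 0.05  # s of raw dwell for a bin to count as visited
MIN_FIELD_PEAK_HZ = 5.0
FIELD_EXTENT_FRACTION = 0.20
MIN_FIELD_BINS_2D = 10
MIN_SPIKES_PER_TRIAL = 300  # active-cell gate for selectivity analyses


@dataclass
class RateMap:
    """Binned, smoothed firing-rate surface (2D) or profile (1D)."""

    bin_edges: tuple[np.ndarray, ...]  # (x_edges, y_edges) or (edges,)
    occupancy_s: np.ndarray  # smoothed dwell time per bin
    raw_occupancy_s: np.ndarray
    rate_hz: np.ndarray
    visited: np.ndarray
    dimensionality: int
    direction: str | None = None  # northbound/southbound for 1D maps


@dataclass
class PlaceField:
    bins: list[tuple[int, ...]]
    peak_rate: float
    size: float  # cm^2 (2D) or cm (1D)
    boundaries: tuple[float, float] | None = None  # 1D: start/end positions (cm)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def centroid(self, ratemap: RateMap) -> np.ndarray:
        """Rate-weighted centroid in cm."""
        idx = np.array(self.bins)
        w = np.array([ratemap.rate_hz[tuple(b)] for b in self.bins])
        centers = [
            (e[:-1] + e[1:]) / 2 for e in ratemap.bin_edges
        ]
        coords = np.stack([centers[d][idx[:, d]] for d in range(idx.shape[1])], axis=1)
        return (coords * w[:, None]).sum(axis=0) / w.sum()


@dataclass
class SelectivityScores:
    information: float  # bits/spike
    sparsity: float


# ---------------------------------------------------------------------------
# Smoothing (mass-conserving Gaussian)
# ---------------------------------------------------------------------------


def _gaussian_kernel(ndim: int, sd_bins: float) -> np.ndarray:
    r = int(np.ceil(3 * sd_bins))
    ax = np.arange(-r, r + 1)
    g1 = np.exp(-(ax**2) / (2 * sd_bins**2))
    if ndim == 1:
        k = g1
    else:
        k = np.outer(g1, g1)
    return k / k.sum()


def _smooth(x: np.ndarray, sd_bins: float = SMOOTH_SD / BIN_SIZE) -> np.ndarray:
    """Gaussian smoothing that conserves total mass at arena edges.

    Each bin's mass is spread with a kernel renormalized to the part that
    falls inside the arena, i.e. ``conv(x / conv(1, K), K)``.
    """
    k = _gaussian_kernel(x.ndim, sd_bins)
    ones = np.ones_like(x, dtype=float)
    m = ndimage.convolve(ones, k, mode="constant", cval=0.0)
    return ndimage.convolve(x / m, k, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------


def _included_samples(
    track: PositionTrack, speed: SpeedSeries, min_speed: float
) -> np.ndarray:
    ok = track.valid & speed.valid & (speed.speed > min_speed)
    return ok


def occupancy_map(
    track: PositionTrack,
    speed: SpeedSeries,
    arena: tuple[float, float],
    min_speed: float = MIN_SPEED,
    bin_size: float = BIN_SIZE,
) -> RateMap:
    """Smoothed dwell time per 2x2 cm bin from fast-running samples."""
    ok = _included_samples(track, speed, min_speed)
    if not ok.any():
        raise ValueError("occupancy_map: no samples above the speed threshold")
    dt = float(np.median(np.diff(track.times)))
    xe = np.arange(0.0, arena[0] + bin_size / 2, bin_size)
    ye = np.arange(0.0, arena[1] + bin_size / 2, bin_size)
    raw, _, _ = np.histogram2d(track.x[ok], track.y[ok], bins=(xe, ye))
    raw *= dt
    smoothed = _smooth(raw)
    visited = raw >= MIN_OCCUPANCY
    return RateMap(
        bin_edges=(xe, ye),
        occupancy_s=smoothed,
        raw_occupancy_s=raw,
        rate_hz=np.zeros_like(raw),
        visited=visited,
        dimensionality=2,
    )


def rate_map(
    spike_times: np.ndarray,
    track: PositionTrack,
    speed: SpeedSeries,
    arena: tuple[float, float],
    min_speed: float = MIN_SPEED,
    bin_size: float = BIN_SIZE,
    smooth_mode: str = "ratio_of_smoothed",
) -> RateMap:
    """Firing-rate map: smoothed spike counts over smoothed occupancy.

    Each spike is assigned to the position sample nearest in time; spikes
    whose nearest sample fails the speed/validity gate are dropped.  With
    ``smooth_mode='smoothed_ratio'`` the raw-count/raw-occupancy ratio is
    smoothed instead (less stable at low occupancy).
    """
    occ = occupancy_map(track, speed, arena, min_speed, bin_size)
    ok = _included_samples(track, speed, min_speed)
    spike_times = np.asarray(spike_times, dtype=float)
    idx = np.clip(np.searchsorted(track.times, spike_times), 0, track.times.size - 1)
    left = np.clip(idx - 1, 0, track.times.size - 1)
    nearer_left = np.abs(track.times[left] - spike_times) < np.abs(
        track.times[idx] - spike_times
    )
    idx[nearer_left] = left[nearer_left]
    keep = ok[idx]
    xe, ye = occ.bin_edges
    counts, _, _ = np.histogram2d(track.x[idx[keep]], track.y[idx[keep]], bins=(xe, ye))
    if smooth_mode == "ratio_of_smoothed":
        sm_counts = _smooth(counts)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(occ.occupancy_s > 0, sm_counts / occ.occupancy_s, 0.0)
    elif smooth_mode == "smoothed_ratio":
        with np.errstate(invalid="ignore", divide="ignore"):
            raw_rate = np.where(occ.raw_occupancy_s > 0, counts / occ.raw_occupancy_s, 0.0)
        rate = _smooth(raw_rate)
    else:
        raise ValueError(f"unknown smooth_mode {smooth_mode!r}")
    rate[~occ.visited] = 0.0
    return RateMap(
        bin_edges=occ.bin_edges,
        occupancy_s=occ.occupancy_s,
        raw_occupancy_s=occ.raw_occupancy_s,
        rate_hz=rate,
        visited=occ.visited,
        dimensionality=2,
    )


# ---------------------------------------------------------------------------
# Place-field detection
# ---------------------------------------------------------------------------


def detect_fields_2d(ratemap: RateMap, min_peak: float = MIN_FIELD_PEAK_HZ) -> list[PlaceField]:
    """Iterative peak-seeded flood fill (4-connected) for 2D place fields.

    Repeat: take the highest unassigned bin above ``min_peak``; flood-fill
    its 4-connected neighborhood down to 20% of that peak; accept the
    region if it has at least 10 bins; remove it and continue.
    """
    rate = ratemap.rate_hz.copy()
    rate[~ratemap.visited] = -np.inf
    assigned = np.zeros_like(rate, dtype=bool)
    fields: list[PlaceField] = []
    bin_area = BIN_SIZE * BIN_SIZE
    while True:
        free = np.where(assigned, -np.inf, rate)
        peak_flat = int(np.argmax(free))
        peak = np.unravel_index(peak_flat, rate.shape)
        peak_rate = free[peak]
        if not np.isfinite(peak_rate) or peak_rate <= min_peak:
            break
        thr = FIELD_EXTENT_FRACTION * peak_rate
        member = (rate >= thr) & ~assigned & np.isfinite(rate)
        labels, _ = ndimage.label(member, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        region = labels == labels[peak]
        assigned |= region
        bins = [tuple(b) for b in np.argwhere(region)]
        if len(bins) >= MIN_FIELD_BINS_2D:
            fields.append(
                PlaceField(bins=bins, peak_rate=float(peak_rate), size=len(bins) * bin_area)
            )
    return fields


def detect_fields_1d(ratemap: RateMap, min_peak: float = MIN_FIELD_PEAK_HZ) -> list[PlaceField]:
    """1D variant: extend from the peak until the rate drops below 20% of it.

    No minimum-size criterion is applied on the line.
    """
    rate = np.where(ratemap.visited, ratemap.rate_hz, -np.inf).astype(float)
    edges = ratemap.bin_edges[0]
    assigned = np.zeros_like(rate, dtype=bool)
    fields: list[PlaceField] = []
    while True:
        free = np.where(assigned, -np.inf, rate)
        p = int(np.argmax(free))
        peak_rate = free[p]
        if not np.isfinite(peak_rate) or peak_rate <= min_peak:
            break
        thr = FIELD_EXTENT_FRACTION * peak_rate
        lo = p
        while lo > 0 and rate[lo - 1] >= thr and not assigned[lo - 1]:
            lo -= 1
        hi = p
        while hi < rate.size - 1 and rate[hi + 1] >= thr and not assigned[hi + 1]:
            hi += 1
        assigned[lo : hi + 1] = True
        bins = [(i,) for i in range(lo, hi + 1)]
        fields.append(
            PlaceField(
                bins=bins,
                peak_rate=float(peak_rate),
                size=(hi - lo + 1) * BIN_SIZE,
                boundaries=(float(edges[lo]), float(edges[hi + 1])),
            )
        )
    return fields


# ---------------------------------------------------------------------------
# Selectivity
# ---------------------------------------------------------------------------


def _p_and_rate(ratemap: RateMap) -> tuple[np.ndarray, np.ndarray]:
    v = ratemap.visited
    occ = ratemap.occupancy_s[v]
    p = occ / occ.sum()
    lam = ratemap.rate_hz[v]
    return p, lam


def spatial_information(ratemap: RateMap) -> float:
    """Skaggs spatial information score in bits/spike.

    ``sum_i p_i (lam_i/lam) log2(lam_i/lam)`` over visited bins, where
    ``p_i`` is the occupancy probability and ``lam`` the overall mean rate.
    """
    p, lam = _p_and_rate(ratemap)
    mean_rate = float(np.sum(p * lam))
    if mean_rate <= 0:
        raise ValueError("spatial_information: zero mean rate")
    rel = lam / mean_rate
    terms = np.where(rel > 0, p * rel * np.log2(np.where(rel > 0, rel, 1.0)), 0.0)
    return float(terms.sum())


def sparsity(ratemap: RateMap) -> float:
    """Skaggs sparsity: ``(sum p lam)^2 / sum p lam^2``, in (0, 1]."""
    p, lam = _p_and_rate(ratemap)
    num = float(np.sum(p * lam)) ** 2
    den = float(np.sum(p * lam**2))
    if den <= 0:
        raise ValueError("sparsity: zero mean rate")
    return num / den


def map_stability(map1: RateMap, map2: RateMap) -> float | None:
    """Pearson correlation of two maps over their common visited bins."""
    if map1.rate_hz.shape != map2.rate_hz.shape:
        raise ValueError("map_stability: different binning")
    common = map1.visited & map2.visited
    if int(common.sum()) < 10:
        return None
    a = map1.rate_hz[common]
    b = map2.rate_hz[common]
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def selectivity(ratemap: RateMap, n_spikes: int) -> SelectivityScores | None:
    """Information and sparsity; None for cells below the 300-spike gate."""
    if n_spikes < MIN_SPIKES_PER_TRIAL:
        return None
    return SelectivityScores(
        information=spatial_information(ratemap), sparsity=sparsity(ratemap)
    )


# ---------------------------------------------------------------------------
# Zigzag-maze linearization
# ---------------------------------------------------------------------------


class ZigzagMaze:
    """Skeleton of the 5-alley zigzag maze and arc-length linearization.

    Five 7 cm wide, 65 cm long alleys run north-south side by side; the
    track passes from each alley to the next through a gap at alternating
    ends.  The skeleton is the alley centerlines joined by half-turns of
    radius 3.5 cm (half the alley width); the 1D coordinate is arc length
    from the south end of alley 1.
    """

    ALLEY_WIDTH = 7.0
    ALLEY_LENGTH = 65.0
    N_ALLEYS = 5
    TURN_RADIUS = 3.5

    def __init__(self, resolution: float = 0.25):
        pts: list[np.ndarray] = []
        r = self.TURN_RADIUS
        y_lo, y_hi = r, self.ALLEY_LENGTH - r
        for i in range(self.N_ALLEYS):
            xc = self.ALLEY_WIDTH / 2 + i * self.ALLEY_WIDTH
            if i % 2 == 0:  # odd alleys run south->north
                y0 = 0.0 if i == 0 else y_lo
                y1 = self.ALLEY_LENGTH if i == self.N_ALLEYS - 1 else y_hi
                ys = np.arange(y0, y1, resolution)
            else:  # even alleys run north->south
                ys = np.arange(y_hi, y_lo, -resolution)
            pts.append(np.column_stack([np.full(ys.size, xc), ys]))
            if i < self.N_ALLEYS - 1:
                # half-turn arc joining this centerline to the next
                cx = xc + self.ALLEY_WIDTH / 2
                if i % 2 == 0:  # turn at the north end
                    cy = y_hi
                    ang = np.linspace(np.pi, 0.0, max(int(np.pi * r / resolution), 8))
                else:  # turn at the south end
                    cy = y_lo
                    ang = np.linspace(np.pi, 2 * np.pi, max(int(np.pi * r / resolution), 8))
                pts.append(
                    np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])
                )
        skel = np.vstack(pts)
        seglen = np.hypot(*np.diff(skel, axis=0).T)
        self.skeleton = skel
        self.arc_length = np.concatenate(([0.0], np.cumsum(seglen)))
        self.total_length = float(self.arc_length[-1])
        self._tree = cKDTree(skel)
        self.extent = (self.N_ALLEYS * self.ALLEY_WIDTH, self.ALLEY_LENGTH)

    def project(self, x: np.ndarray, y: np.ndarray, tolerance: float = 5.0):
        """Project samples onto the skeleton; returns (linear_pos, valid)."""
        d, idx = self._tree.query(np.column_stack([x, y]))
        valid = d <= self.ALLEY_WIDTH / 2 + tolerance
        return self.arc_length[idx], valid

    def point_at(self, s: np.ndarray) -> np.ndarray:
        """Inverse map: 2D skeleton point at arc length ``s`` (cm)."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.total_length)
        xi = np.interp(s, self.arc_length, self.skeleton[:, 0])
        yi = np.interp(s, self.arc_length, self.skeleton[:, 1])
        return np.column_stack([xi, yi])


def linearize_zigzag(
    track: PositionTrack,
    maze: ZigzagMaze | None = None,
    end_zone: float = 8.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearize a zigzag-maze track and label run direction per sample.

    Returns ``(linear_cm, direction, valid)`` where direction is +1 for
    northbound samples (running toward the far end of alley 5), -1 for
    southbound, and 0 outside complete end-to-end runs.  Runs are split at
    visits to the two maze ends (within ``end_zone`` cm of either end).
    """
    maze = maze or ZigzagMaze()
    lin, ok = maze.project(track.x, track.y)
    ok &= track.valid
    L = maze.total_length
    direction = np.zeros(track.times.size, dtype=int)
    at_south = ok & (lin <= end_zone)
    at_north = ok & (lin >= L - end_zone)
    # walk through end visits and label the stretch between opposite ends
    state = 0  # last end seen: 0 none, -1 south, +1 north
    last_end_idx = 0
    for i in range(track.times.size):
        if at_south[i]:
            if state == 1:
                direction[last_end_idx : i + 1] = np.where(
                    ok[last_end_idx : i + 1], -1, 0
                )
            state = -1
            last_end_idx = i
        elif at_north[i]:
            if state == -1:
                direction[last_end_idx : i + 1] = np.where(
                    ok[last_end_idx : i + 1], 1, 0
                )
            state = 1
            last_end_idx = i
    return lin, direction, ok


def linear_rate_map(
    spike_times: np.ndarray,
    track: PositionTrack,
    speed: SpeedSeries,
    linear: np.ndarray,
    sample_ok: np.ndarray,
    total_length: float,
    direction_label: str | None = None,
    min_speed: float = MIN_SPEED,
    bin_size: float = BIN_SIZE,
) -> RateMap:
    """1D firing-rate profile along the linearized maze (one run direction)."""
    ok = sample_ok & speed.valid & (speed.speed > min_speed)
    if not ok.any():
        raise ValueError("linear_rate_map: no included samples")
    dt = float(np.median(np.diff(track.times)))
    edges = np.arange(0.0, total_length + bin_size / 2, bin_size)
    raw, _ = np.histogram(linear[ok], bins=edges)
    raw = raw * dt
    occ = _smooth(raw)
    spike_times = np.asarray(spike_times, dtype=float)
    idx = np.clip(np.searchsorted(track.times, spike_times), 0, track.times.size - 1)
    left = np.clip(idx - 1, 0, track.times.size - 1)
    nearer_left = np.abs(track.times[left] - spike_times) < np.abs(track.times[idx] - spike_times)
    idx[nearer_left] = left[nearer_left]
    keep = ok[idx]
    counts, _ = np.histogram(linear[idx[keep]], bins=edges)
    sm_counts = _smooth(counts.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ > 0, sm_counts / occ, 0.0)
    visited = raw >= MIN_OCCUPANCY
    rate[~visited] = 0.0
    return RateMap(
        bin_edges=(edges,),
        occupancy_s=occ,
        raw_occupancy_s=raw,
        rate_hz=rate,
        visited=visited,
        dimensionality=1,
        direction=direction_label,
    )
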
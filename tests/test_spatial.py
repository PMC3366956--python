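"""Rate maps, place-field detection, selectivity and maze linearization."""

import numpy as np
import pytest

from hippocode.session_io import PositionTrack, compute_speed
from hippocode.spatial import (
    BIN_SIZE,
    MIN_SPIKES_PER_TRIAL,
    RateMap,
    ZigzagMaze,
    _smooth,
    detect_fields_1d,
    detect_fields_2d,
    linearize_zigzag,
    map_stability,
    occupancy_map,
    rate_map,
    selectivity,
    sparsity,
    spatial_information,
)


def _uniform_map(rates):
    rates = np.asarray(rates, dtype=float)
    occ = np.ones_like(rates)
    edges = tuple(np.arange(s + 1) * BIN_SIZE for s in rates.shape)
    return RateMap(
        bin_edges=edges,
        occupancy_s=occ,
        raw_occupancy_s=occ,
        rate_hz=rates,
        visited=np.ones_like(rates, dtype=bool),
        dimensionality=rates.ndim,
    )


# ---------------------------------------------------------------------------
# Information and sparsity identities
# ---------------------------------------------------------------------------


def test_one_hot_cell_information_is_log2_n():
    for n in (4, 16, 100):
        rates = np.zeros(n)
        rates[2] = 5.0
        rm = _uniform_map(rates)
        assert spatial_information(rm) == pytest.approx(np.log2(n), abs=1e-12)
        assert sparsity(rm) == pytest.approx(1.0 / n, abs=1e-12)


def test_uniform_cell_information_zero_sparsity_one():
    rm = _uniform_map(np.full((10, 10), 3.0))
    assert spatial_information(rm) == pytest.approx(0.0, abs=1e-12)
    assert sparsity(rm) == pytest.approx(1.0, abs=1e-12)


def test_information_nonnegative_on_random_maps():
    rng = np.random.default_rng(0)
    for _ in range(50):
        rm = _uniform_map(rng.uniform(0, 10, (8, 8)))
        assert spatial_information(rm) >= -1e-12
        s = sparsity(rm)
        assert 0.0 < s <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def test_smoothing_conserves_mass():
    rng = np.random.default_rng(1)
    for shape in [(20,), (15, 18)]:
        x = rng.uniform(0, 5, shape)
        y = _smooth(x)
        assert y.sum() == pytest.approx(x.sum(), rel=1e-9)


def test_smoothing_is_linear_and_ratio_of_smoothed_is_exact_for_proportional_maps():
    rng = np.random.default_rng(9)
    occ = rng.uniform(0.5, 3.0, (12, 12))
    np.testing.assert_allclose(_smooth(3.0 * occ), 3.0 * _smooth(occ), rtol=1e-12)
    # spike counts exactly proportional to occupancy -> constant rate map,
    # edge bias cancels in the ratio of smoothed maps
    counts = 4.2 * occ
    rate = _smooth(counts) / _smooth(occ)
    np.testing.assert_allclose(rate, 4.2, rtol=1e-9)


def test_smoothing_spreads_a_delta_symmetrically():
    x = np.zeros((21, 21))
    x[10, 10] = 1.0
    y = _smooth(x)
    assert y.sum() == pytest.approx(1.0, rel=1e-9)
    np.testing.assert_allclose(y, y[::-1, :], atol=1e-12)
    np.testing.assert_allclose(y, y[:, ::-1], atol=1e-12)
    assert y[10, 10] == y.max()


# ---------------------------------------------------------------------------
# Occupancy and rate maps
# ---------------------------------------------------------------------------


def _walk(duration=120.0, fs=25.0, seed=2, box=70.0):
    rng = np.random.default_rng(seed)
    t = np.arange(0, duration, 1 / fs)
    x = np.empty(t.size)
    y = np.empty(t.size)
    x[0] = y[0] = box / 2
    v = np.zeros(2)
    for i in range(1, t.size):
        v = 0.9 * v + rng.normal(0, 0.7, 2)
        x[i] = np.clip(x[i - 1] + v[0], 1, box - 1)
        y[i] = np.clip(y[i - 1] + v[1], 1, box - 1)
    return PositionTrack(times=t, x=x, y=y, valid=np.ones(t.size, bool))


def test_occupancy_totals_match_gated_time():
    track = _walk()
    speed = compute_speed(track)
    occ = occupancy_map(track, speed, (70.0, 70.0))
    ok = speed.valid & (speed.speed > 3.0) & track.valid
    want = ok.sum() * (1.0 / 25.0)
    assert occ.raw_occupancy_s.sum() == pytest.approx(want, rel=1e-9)
    # smoothing conserves total occupancy
    assert occ.occupancy_s.sum() == pytest.approx(want, rel=1e-9)


def test_rate_map_recovers_mean_rate():
    track = _walk(duration=240.0)
    speed = compute_speed(track)
    rng = np.random.default_rng(3)
    spikes = np.sort(rng.uniform(0, 240.0, 2000))  # homogeneous firing
    rm = rate_map(spikes, track, speed, (70.0, 70.0))
    # total spikes recovered: sum(rate * occupancy) == gated spike count
    got = np.sum(rm.rate_hz * rm.occupancy_s)
    ok = speed.valid & (speed.speed > 3.0) & track.valid
    idx = np.clip(np.searchsorted(track.times, spikes), 0, track.times.size - 1)
    # uniform firing over a well-covered arena: map roughly flat
    mean_rate = got / rm.occupancy_s.sum()
    assert mean_rate == pytest.approx(2000 / 240.0, rel=0.25)
    assert (rm.rate_hz >= 0).all()


def test_rate_map_modes_agree_on_dense_coverage():
    track = _walk(duration=240.0)
    speed = compute_speed(track)
    spikes = np.sort(np.random.default_rng(4).uniform(0, 240.0, 3000))
    a = rate_map(spikes, track, speed, (70.0, 70.0), smooth_mode="ratio_of_smoothed")
    b = rate_map(spikes, track, speed, (70.0, 70.0), smooth_mode="smoothed_ratio")
    common = a.visited & b.visited & (a.raw_occupancy_s > 0.5)
    if common.sum() > 20:
        corr = np.corrcoef(a.rate_hz[common], b.rate_hz[common])[0, 1]
        assert corr > 0.5


# ---------------------------------------------------------------------------
# Field detection
# ---------------------------------------------------------------------------


def _brute_fields_2d(rate, visited, min_peak=5.0, frac=0.20, min_bins=10):
    """Independent BFS flood-fill implementation."""
    r = rate.copy().astype(float)
    r[~visited] = -np.inf
    assigned = np.zeros(r.shape, bool)
    fields = []
    while True:
        free = np.where(assigned, -np.inf, r)
        p = np.unravel_index(int(np.argmax(free)), r.shape)
        if not np.isfinite(free[p]) or free[p] <= min_peak:
            break
        thr = frac * free[p]
        stack = [p]
        region = set()
        while stack:
            i, j = stack.pop()
            if (i, j) in region:
                continue
            if not (0 <= i < r.shape[0] and 0 <= j < r.shape[1]):
                continue
            if assigned[i, j] or not np.isfinite(r[i, j]) or r[i, j] < thr:
                continue
            region.add((i, j))
            stack.extend([(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)])
        for i, j in region:
            assigned[i, j] = True
        if len(region) >= min_bins:
            fields.append(frozenset(region))
    return fields


def test_field_detection_matches_brute_force_flood_fill():
    rng = np.random.default_rng(5)
    n_with_fields = 0
    for _ in range(100):
        base = rng.uniform(0, 2, (15, 15))
        for _ in range(rng.integers(0, 3)):
            ci, cj = rng.integers(2, 13, 2)
            ii, jj = np.mgrid[0:15, 0:15]
            base += rng.uniform(6, 12) * np.exp(
                -((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * rng.uniform(1.0, 2.5) ** 2)
            )
        visited = rng.uniform(0, 1, (15, 15)) > 0.05
        rm = _uniform_map(base)
        rm = RateMap(
            bin_edges=rm.bin_edges,
            occupancy_s=rm.occupancy_s,
            raw_occupancy_s=rm.raw_occupancy_s,
            rate_hz=base,
            visited=visited,
            dimensionality=2,
        )
        got = [frozenset(tuple(b) for b in f.bins) for f in detect_fields_2d(rm)]
        want = _brute_fields_2d(base, visited)
        assert got == want
        n_with_fields += bool(want)
    assert n_with_fields > 20  # the comparison actually exercised fields


def test_1d_field_extends_to_20_percent_of_peak():
    rates = np.full(100, 0.5)
    rates[40:61] = 10.0 * np.exp(-((np.arange(40, 61) - 50.0) ** 2) / (2 * 4.0**2))
    rm = _uniform_map(rates)
    fields = detect_fields_1d(rm)
    assert len(fields) == 1
    f = fields[0]
    thr = 0.2 * rates.max()
    inside = {b[0] for b in f.bins}
    # every in-field bin is above threshold; the bins adjacent to the field
    # boundary are below it (or field reaches an edge)
    assert all(rates[i] >= thr for i in inside)
    lo, hi = min(inside), max(inside)
    assert lo == 0 or rates[lo - 1] < thr
    assert hi == 99 or rates[hi + 1] < thr
    assert f.boundaries is not None
    assert f.boundaries[0] == pytest.approx(lo * BIN_SIZE)


def test_no_fields_below_peak_threshold():
    rm = _uniform_map(np.full(50, 4.9))
    assert detect_fields_1d(rm) == []
    rm2 = _uniform_map(np.full((12, 12), 4.9))
    assert detect_fields_2d(rm2) == []


def test_2d_fields_require_minimum_size():
    rates = np.zeros((20, 20))
    rates[5, 5] = 20.0  # single-bin spike of rate: too small to be a field
    rm = _uniform_map(rates)
    assert detect_fields_2d(rm) == []


# ---------------------------------------------------------------------------
# Stability and selectivity gating
# ---------------------------------------------------------------------------


def test_map_stability_matches_pearson():
    rng = np.random.default_rng(6)
    for _ in range(100):
        a = _uniform_map(rng.uniform(0, 10, (8, 8)))
        noise = rng.normal(0, 1, (8, 8))
        b = _uniform_map(np.clip(a.rate_hz + noise, 0, None))
        got = map_stability(a, b)
        want = np.corrcoef(a.rate_hz.ravel(), b.rate_hz.ravel())[0, 1]
        assert got == pytest.approx(want, rel=1e-9)


def test_map_stability_none_for_degenerate_input():
    a = _uniform_map(np.full((8, 8), 2.0))
    b = _uniform_map(np.random.default_rng(7).uniform(0, 5, (8, 8)))
    assert map_stability(a, b) is None  # zero variance in a
    tiny = _uniform_map(np.array([[1.0, 2.0], [3.0, 4.0]]))
    assert map_stability(tiny, tiny) is None  # < 10 common bins


def test_selectivity_gate_at_300_spikes():
    rm = _uniform_map(np.random.default_rng(8).uniform(0, 10, (10, 10)))
    assert selectivity(rm, MIN_SPIKES_PER_TRIAL - 1) is None
    scores = selectivity(rm, MIN_SPIKES_PER_TRIAL)
    assert scores is not None
    assert scores.information == pytest.approx(spatial_information(rm))


# ---------------------------------------------------------------------------
# Zigzag maze
# ---------------------------------------------------------------------------


def test_maze_total_length_and_endpoints():
    maze = ZigzagMaze()
    # 5 alleys of 65 cm (centerline 58 cm between turn centers... geometry
    # checked via endpoints): south end maps to 0, north end to total length
    assert maze.total_length > 300.0
    p0 = maze.point_at(np.array([0.0]))[0]
    p1 = maze.point_at(np.array([maze.total_length]))[0]
    s0, _ = maze.project(np.array([p0[0]]), np.array([p0[1]]))
    s1, _ = maze.project(np.array([p1[0]]), np.array([p1[1]]))
    assert s0[0] == pytest.approx(0.0, abs=0.5)
    assert s1[0] == pytest.approx(maze.total_length, abs=0.5)


def test_project_point_at_roundtrip_on_skeleton():
    maze = ZigzagMaze()
    s = np.linspace(0.5, maze.total_length - 0.5, 200)
    pts = maze.point_at(s)
    s_back, ok = maze.project(pts[:, 0], pts[:, 1])
    assert ok.all()
    np.testing.assert_allclose(s_back, s, atol=0.3)


def test_linearization_labels_end_to_end_runs():
    maze = ZigzagMaze()
    fs = 25.0
    # synthetic back-and-forth runs along the skeleton at 15 cm/s
    L = maze.total_length
    s_up = np.arange(0, L, 15.0 / fs)
    s_down = s_up[::-1]
    s = np.concatenate([s_up, s_down, s_up])
    pts = maze.point_at(s)
    t = np.arange(s.size) / fs
    track = PositionTrack(times=t, x=pts[:, 0], y=pts[:, 1], valid=np.ones(s.size, bool))
    lin, direction, ok = linearize_zigzag(track, maze)
    assert ok.mean() > 0.95
    n = s_up.size
    mid = slice(n // 4, 3 * n // 4)
    assert (direction[mid] == 1).all()
    mid_down = slice(n + n // 4, n + 3 * n // 4)
    assert (direction[mid_down] == -1).all()
    np.testing.assert_allclose(lin[ok], s[ok], atol=1.0)
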
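"""Per-session orchestration and group-level statistics.

``run_session`` executes the full analysis chain — SWR detection and
characterization, theta epochs and phase, unit classification, open-field
and zigzag rate maps with selectivity, theta/ripple phase locking, and
phase precession — and returns (optionally writes) tabular products.
Group comparisons use Wilcoxon's rank-sum test (normal approximation with
tie correction) for linear metrics and Watson's U^2 for circular ones.
"""

from __future__ import annotations

import os
import sys
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import oscillations as osc
from . import phase as ph
from . import spatial as sp
from . import units as un
from .session_io import RecordingSession, compute_speed, restrict
from .spatial import ZigzagMaze

__all__ = [
    "run_session",
    "compare_groups",
    "rank_sum",
    "SessionResults",
]

RAYLEIGH_ALPHA = 0.01  # modulation classification threshold
PRECESSION_ALPHA = 0.05  # significant precession: p below this AND r < 0


@dataclass
class SessionResults:
    swr: pd.DataFrame
    theta_epochs: pd.DataFrame
    units: pd.DataFrame
    selectivity: pd.DataFrame
    theta_phase: pd.DataFrame
    ripple_phase: pd.DataFrame
    precession: pd.DataFrame
    errors: dict[str, str]

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        for name in ("swr", "theta_epochs", "units", "selectivity", "theta_phase", "ripple_phase", "precession"):
            df = getattr(self, name)
            df.to_csv(os.path.join(outdir, f"{name}.csv"), index=False, float_format="%.10g")


def _log(verbose: bool, msg: str) -> None:
    if verbose:
        print(msg, file=sys.stderr)


def run_session(
    session: RecordingSession,
    cfg: osc.OscillationConfig | None = None,
    outdir: str | None = None,
    seed: int = 0,
    verbose: bool = False,
    n_permutations: int = 200,
) -> SessionResults:
    """Run the whole analysis chain on one session; deterministic given
    the session, config and seed (used only for permutation tests)."""
    cfg = cfg or osc.OscillationConfig()
    errors: dict[str, str] = {}
    t_start = time.time()
    chan = session.pyramidal_layer_channels[0]
    fs = chan.sample_rate
    ref = session.reference_channel
    rest = session.trial_intervals("rest")

    # --- SWR ---
    swr_rows = []
    epochs: list[osc.SwrEpoch] = []
    filtered = osc.bandpass(chan.samples, fs, cfg.ripple_band, cfg.filter_order)
    try:
        power = osc.windowed_rms(filtered, fs, cfg.rms_window, cfg.rms_step,
                                 baseline_epochs=rest or None)
        ref_power = None
        if ref is not None:
            ref_filt = osc.bandpass(ref.samples, ref.sample_rate, cfg.ripple_band, cfg.filter_order)
            ref_power = osc.windowed_rms(ref_filt, ref.sample_rate, cfg.rms_window, cfg.rms_step,
                                         baseline_epochs=rest or None)
        epochs = [
            osc.characterize_swr(ep, filtered, fs, power, cfg)
            for ep in osc.detect_swr(power, ref_power, cfg)
        ]
        for ep in epochs:
            swr_rows.append(
                dict(start=ep.start, end=ep.end, peak_time=ep.peak_power_time,
                     peak_freq_hz=ep.peak_frequency, amplitude=ep.amplitude,
                     duration_s=ep.duration)
            )
    except Exception as e:  # noqa: BLE001 - stage errors are reported, not fatal
        errors["swr"] = str(e)
    swr_df = pd.DataFrame(swr_rows, columns=["start", "end", "peak_time", "peak_freq_hz", "amplitude", "duration_s"])
    _log(verbose, f"[swr] {len(swr_df)} epochs ({time.time() - t_start:.1f}s)")

    # --- theta ---
    theta_epochs: list[tuple[float, float]] = []
    phase_series = None
    try:
        theta_epochs = osc.detect_theta_epochs(chan.samples, fs, cfg)
        phase_series = osc.theta_phase_series(chan.samples, fs, theta_epochs, cfg)
    except Exception as e:  # noqa: BLE001
        errors["theta"] = str(e)
    theta_df = pd.DataFrame(theta_epochs, columns=["start", "end"])
    _log(verbose, f"[theta] {len(theta_df)} epochs ({time.time() - t_start:.1f}s)")

    # --- units: features + classification ---
    duration = session.trials[-1].end - session.trials[0].start if session.trials else chan.duration
    unit_rows = []
    feats_by_unit: dict[str, un.UnitFeatures] = {}
    for u in session.units:
        try:
            feats_by_unit[u.unit_id] = un.unit_features(u, duration)
        except Exception as e:  # noqa: BLE001
            errors[f"units:{u.unit_id}"] = str(e)

    # spatial maps first (the template needs spatially selective units)
    speed = compute_speed(session.track)
    open_trials = session.trial_intervals("open_field")
    sel_rows = []
    info_by_unit: dict[str, float] = {}
    maps_by_unit: dict[str, sp.RateMap] = {}
    if open_trials:
        from .session_io import restrict_track

        tr1 = restrict_track(session.track, [open_trials[0]])
        sp1 = compute_speed(tr1)
        for u in session.units:
            spikes = restrict(u.spike_times, [open_trials[0]])
            try:
                rm = sp.rate_map(spikes, tr1, sp1, arena=(70.0, 70.0))
            except Exception as e:  # noqa: BLE001
                errors[f"maps:{u.unit_id}"] = str(e)
                continue
            maps_by_unit[u.unit_id] = rm
            if spikes.size >= sp.MIN_SPIKES_PER_TRIAL:
                try:
                    info = sp.spatial_information(rm)
                    spars = sp.sparsity(rm)
                    fields = sp.detect_fields_2d(rm)
                    info_by_unit[u.unit_id] = info
                    sel_rows.append(
                        dict(unit_id=u.unit_id, n_spikes=spikes.size, info_bits=info,
                             sparsity=spars, n_fields=len(fields),
                             peak_hz=float(rm.rate_hz.max()),
                             field_size=fields[0].size if fields else np.nan)
                    )
                except Exception as e:  # noqa: BLE001
                    errors[f"selectivity:{u.unit_id}"] = str(e)
    sel_df = pd.DataFrame(sel_rows, columns=["unit_id", "n_spikes", "info_bits", "sparsity", "n_fields", "peak_hz", "field_size"])

    # template from spatially selective units (info > 0.5)
    ref_feats = [feats_by_unit[uid] for uid, i in info_by_unit.items() if i > 0.5 and uid in feats_by_unit]
    template = None
    if len(ref_feats) >= 4:
        template = un.build_template(ref_feats)
    for u in session.units:
        f = feats_by_unit.get(u.unit_id)
        row = dict(unit_id=u.unit_id, rate_hz=np.nan, ac_moment_ms=np.nan,
                   duration_ms=np.nan, distance=np.nan, label="unclassified")
        if f is not None:
            row.update(rate_hz=f.mean_rate, ac_moment_ms=f.ac_first_moment, duration_ms=f.spike_duration)
            if template is not None:
                d = un.mahalanobis(f, template)
                row.update(distance=d, label=un.classify(d).label)
        unit_rows.append(row)
    units_df = pd.DataFrame(unit_rows, columns=["unit_id", "rate_hz", "ac_moment_ms", "duration_ms", "distance", "label"])
    _log(verbose, f"[units] template from {len(ref_feats)} reference units ({time.time() - t_start:.1f}s)")

    # --- phase locking ---
    theta_rows = []
    ripple_rows = []
    rps = None
    if epochs:
        try:
            rps = osc.ripple_phase_series(filtered, fs, epochs)
        except Exception as e:  # noqa: BLE001
            errors["ripple_phase"] = str(e)
    for u in session.units:
        if phase_series is not None:
            phases, dropped = ph.phases_of_spikes(u.spike_times, phase_series)
            if phases.size:
                st = ph.circ_stats(phases)
                theta_rows.append(
                    dict(unit_id=u.unit_id, n=st.n, mean_phase_deg=st.mean_phase,
                         vector_length=st.vector_length, rayleigh_p=st.rayleigh_p,
                         n_dropped=dropped)
                )
        if rps is not None:
            rphases, rdropped = ph.phases_of_spikes(u.spike_times, rps)
            if rphases.size:
                st = ph.circ_stats(rphases)
                ripple_rows.append(
                    dict(unit_id=u.unit_id, n=st.n, mean_phase_deg=st.mean_phase,
                         vector_length=st.vector_length, rayleigh_p=st.rayleigh_p,
                         n_dropped=rdropped)
                )
    cols = ["unit_id", "n", "mean_phase_deg", "vector_length", "rayleigh_p", "n_dropped"]
    theta_phase_df = pd.DataFrame(theta_rows, columns=cols)
    ripple_phase_df = pd.DataFrame(ripple_rows, columns=cols)
    _log(verbose, f"[phase] ({time.time() - t_start:.1f}s)")

    # --- precession on the zigzag maze (first zigzag trial) ---
    prec_rows = []
    zig = session.trial_intervals("zigzag")
    if zig and phase_series is not None:
        try:
            from .session_io import restrict_track

            tz = restrict_track(session.track, [zig[0]])
            spz = compute_speed(tz)
            maze = ZigzagMaze()
            lin, direction, ok = sp.linearize_zigzag(tz, maze)
            for d_label, d_sign in (("northbound", 1), ("southbound", -1)):
                sample_ok = ok & (direction == d_sign)
                if sample_ok.sum() < 10:
                    continue
                for u in session.units:
                    spikes = restrict(u.spike_times, [zig[0]])
                    if spikes.size < 10:
                        continue
                    try:
                        rm = sp.linear_rate_map(spikes, tz, spz, lin, sample_ok,
                                                maze.total_length, direction_label=d_label)
                    except ValueError:
                        continue
                    for fi, fld in enumerate(sp.detect_fields_1d(rm)):
                        lo, hi = fld.boundaries
                        idx = np.clip(np.searchsorted(tz.times, spikes), 1, tz.times.size - 1)
                        near = np.where(
                            np.abs(tz.times[idx - 1] - spikes) < np.abs(tz.times[idx] - spikes),
                            idx - 1, idx,
                        )
                        pos = lin[near]
                        in_field = (pos >= lo) & (pos < hi) & sample_ok[near]
                        if in_field.sum() < 10:
                            continue
                        phases, _ = ph.phases_of_spikes(spikes[in_field], phase_series)
                        if phases.size < 10:
                            continue
                        rel = (pos[in_field][: phases.size] - lo) / (hi - lo)
                        if d_sign < 0:
                            rel = 1.0 - rel
                        fit = ph.precession_fit(phases, rel, n_permutations=n_permutations, seed=seed)
                        prec_rows.append(
                            dict(unit_id=u.unit_id, direction=d_label, field_id=fi,
                                 slope=fit.slope, r=fit.r, p=fit.p, n_spikes=fit.n,
                                 significant=bool(fit.p < PRECESSION_ALPHA and fit.r < 0))
                        )
        except Exception as e:  # noqa: BLE001
            errors["precession"] = str(e)
    prec_df = pd.DataFrame(prec_rows, columns=["unit_id", "direction", "field_id", "slope", "r", "p", "n_spikes", "significant"])
    _log(verbose, f"[precession] {len(prec_df)} fields ({time.time() - t_start:.1f}s)")

    results = SessionResults(
        swr=swr_df, theta_epochs=theta_df, units=units_df, selectivity=sel_df,
        theta_phase=theta_phase_df, ripple_phase=ripple_phase_df,
        precession=prec_df, errors=errors,
    )
    if outdir is not None:
        results.write(outdir)
    return results


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


def rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum test, normal approximation with tie correction.

    Returns (z, two-sided p).  The statistic is the rank sum of sample a.
    """
    from scipy.stats import norm

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.size, b.size
    pooled = np.concatenate([a, b])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(pooled.size)
    ranks[order] = np.arange(1, pooled.size + 1)
    # average ranks for ties
    uniq, inv, counts = np.unique(pooled, return_inverse=True, return_counts=True)
    cum = np.concatenate(([0], np.cumsum(counts)))
    avg_rank = (cum[:-1] + cum[1:] + 1) / 2.0
    ranks = avg_rank[inv]
    W = ranks[:n].sum()
    N = n + m
    mu = n * (N + 1) / 2.0
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1)) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (W - mu) / np.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def compare_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    circular: bool = False,
) -> dict:
    """Compare a metric between two unit (or mouse) populations.

    Linear metrics: Wilcoxon rank-sum with group medians.  Circular
    metrics (degrees): Watson's U^2 with group circular means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("compare_groups: need >= 3 observations per group")
    if circular:
        u2, sig = ph.watson_two_sample(a, b)
        return dict(
            test="watson_u2", statistic=u2, significant_at=sig,
            mean_a=ph.circ_stats(a).mean_phase, mean_b=ph.circ_stats(b).mean_phase,
        )
    z, p = rank_sum(a, b)
    return dict(
        test="rank_sum", statistic=z, p=p,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
    )
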
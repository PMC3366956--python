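"""Per-unit physiological features and pyramidal/interneuron classification.

Units are characterized by three features: session-wide mean firing rate,
the first moment of the spike-time autocorrelation within a 25 ms window,
and the spike duration measured at 25% of the maximum waveform amplitude.
A template (mean + covariance) built from reference pyramidal cells
(spatially selective units) defines a Mahalanobis distance for every unit:
< 20 -> pyramidal, > 40 -> interneuron, in between -> unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .session_io import Unit

__all__ = [
    "UnitFeatures",
    "PyramidalTemplate",
    "UnitClass",
    "spike_duration_at_25pct",
    "autocorr_first_moment",
    "unit_features",
    "build_template",
    "mahalanobis",
    "classify",
    "isolation_distance",
    "PYRAMIDAL_MAX_DISTANCE",
    "INTERNEURON_MIN_DISTANCE",
]

PYRAMIDAL_MAX_DISTANCE = 20.0
INTERNEURON_MIN_DISTANCE = 40.0


@dataclass
class UnitFeatures:
    mean_rate: float  # Hz, whole session
    ac_first_moment: float  # ms
    spike_duration: float  # ms

    def as_vector(self, log_rate: bool = True) -> np.ndarray:
        r = np.log10(self.mean_rate) if log_rate else self.mean_rate
        return np.array([r, self.ac_first_moment, self.spike_duration])


@dataclass
class PyramidalTemplate:
    mean_vector: np.ndarray  # (3,)
    covariance: np.ndarray  # (3, 3) symmetric positive definite
    log_rate: bool = True


@dataclass
class UnitClass:
    label: str  # pyramidal | interneuron | unclassified
    distance: float


def spike_duration_at_25pct(mean_waveform: np.ndarray, waveform_rate: float) -> float:
    """Spike width (ms) at 25% of the maximum amplitude.

    The width is the length of the interval around the waveform's global
    extremum over which ``|waveform| >= 0.25 * max|waveform|``, with the two
    boundary crossings located by linear interpolation.
    """
    w = np.abs(np.asarray(mean_waveform, dtype=float))
    peak = w.max()
    if peak == 0:
        raise ValueError("flat waveform")
    thr = 0.25 * peak
    p = int(np.argmax(w))
    # walk left
    i = p
    while i > 0 and w[i - 1] >= thr:
        i -= 1
    if i > 0:
        left = (i - 1) + (thr - w[i - 1]) / (w[i] - w[i - 1])
    else:
        left = 0.0
    # walk right
    j = p
    while j < w.size - 1 and w[j + 1] >= thr:
        j += 1
    if j < w.size - 1:
        right = j + (w[j] - thr) / (w[j] - w[j + 1])
    else:
        right = float(w.size - 1)
    return (right - left) / waveform_rate * 1000.0


def autocorr_first_moment(
    spike_times: np.ndarray, window_ms: float = 25.0, bin_ms: float = 0.5
) -> float:
    """First moment (ms) of the spike-time autocorrelation within ``window_ms``.

    All positive pairwise lags up to the window are histogrammed in
    ``bin_ms`` bins; the count-weighted mean of the bin centers is returned.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size < 2:
        raise ValueError("need >= 2 spikes")
    window = window_ms / 1000.0
    # two-pointer sweep collecting positive lags <= window
    lags: list[np.ndarray] = []
    hi = np.searchsorted(t, t + window, side="right")
    for i in range(t.size - 1):
        if hi[i] > i + 1:
            lags.append(t[i + 1 : hi[i]] - t[i])
    if not lags:
        raise ValueError("no lags within window")
    all_lags = np.concatenate(lags) * 1000.0  # ms
    n_bins = int(round(window_ms / bin_ms))
    counts, edges = np.histogram(all_lags, bins=n_bins, range=(0.0, window_ms))
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    if total == 0:
        raise ValueError("no lags within window")
    return float(np.sum(counts * centers) / total)


def unit_features(unit: Unit, session_duration: float, window_ms: float = 25.0) -> UnitFeatures:
    """Compute the three classification features for one unit."""
    if unit.mean_waveform is None or unit.waveform_rate is None:
        raise ValueError(f"unit {unit.unit_id}: waveform required for features")
    return UnitFeatures(
        mean_rate=unit.n_spikes / session_duration,
        ac_first_moment=autocorr_first_moment(unit.spike_times, window_ms=window_ms),
        spike_duration=spike_duration_at_25pct(unit.mean_waveform, unit.waveform_rate),
    )


def build_template(features: list[UnitFeatures] | np.ndarray, log_rate: bool = True) -> PyramidalTemplate:
    """Mean and sample covariance of the reference units' feature vectors.

    A near-singular covariance is regularized by adding 1e-6 * trace/3 to
    the diagonal so that distances stay finite for degenerate references.
    """
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
    else:
        X = np.vstack([f.as_vector(log_rate=log_rate) for f in features])
    if X.shape[0] < 4:
        raise ValueError("need >= 4 reference units for a nonsingular covariance")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    # regularize if near-singular
    if np.linalg.cond(cov) > 1e10 or np.linalg.det(cov) <= 0:
        cov = cov + np.eye(3) * (1e-6 * np.trace(cov) / 3 + 1e-12)
    return PyramidalTemplate(mean_vector=mean, covariance=cov, log_rate=log_rate)


def mahalanobis(x: np.ndarray | UnitFeatures, template: PyramidalTemplate) -> float:
    if isinstance(x, UnitFeatures):
        x = x.as_vector(log_rate=template.log_rate)
    d = np.asarray(x, dtype=float) - template.mean_vector
    return float(np.sqrt(d @ np.linalg.solve(template.covariance, d)))


def classify(distance: float) -> UnitClass:
    """Label a unit from its Mahalanobis distance to the pyramidal template."""
    if distance < 0:
        raise ValueError("negative distance")
    if distance < PYRAMIDAL_MAX_DISTANCE:
        label = "pyramidal"
    elif distance > INTERNEURON_MIN_DISTANCE:
        label = "interneuron"
    else:
        label = "unclassified"
    return UnitClass(label=label, distance=float(distance))


def isolation_distance(
    cluster_features: np.ndarray,
    noise_features: np.ndarray,
    squared: bool = False,
) -> float:
    """Cluster-quality metric: n-th smallest Mahalanobis distance of noise
    spikes from the cluster, where n is the cluster spike count.

    With ``squared=True`` the conventional squared-distance variant is
    returned instead.  If there are fewer noise spikes than cluster spikes
    the metric is undefined and reported as infinity.
    """
    X = np.asarray(cluster_features, dtype=float)
    N = np.asarray(noise_features, dtype=float)
    n = X.shape[0]
    if N.shape[0] < n:
        warnings.warn("isolation_distance undefined: fewer noise than cluster spikes")
        return float("inf")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    if X.shape[1] == 1:
        cov = np.atleast_2d(cov)
    cov = cov + np.eye(cov.shape[0]) * (1e-9 * np.trace(cov) / cov.shape[0] + 1e-15)
    d = N - mean
    d2 = np.einsum("ij,ij->i", d, np.linalg.solve(cov, d.T).T)
    d2 = np.sort(d2)
    val = d2[n - 1]
    return float(val if squared else np.sqrt(val))
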
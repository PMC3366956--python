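# Methods

Models, parameters and numerical choices. Everything here is
implemented in `src/hippocode/` and verified in `tests/`; nothing in
this note asserts empirical results beyond what the test suite
computes.

## Data model (`session_io`)

A `RecordingSession` bundles LFP channels (one flagged pyramidal-layer
channel, optionally one reference channel outside the layer), sorted
units (spike times, mean waveform at its own sampling rate, optional
cluster features), a 25 Hz position track with a validity mask, and
non-overlapping labelled trial epochs. Sessions serialize to a plain
directory: `session.yaml`, little-endian float32 `lfp_<ch>.bin`, CSV
spike/waveform/track tables written with `%.17g` and read with exact
(`round_trip`) float parsing so that write→read→write is
byte-identical.

Speed is computed from boxcar-smoothed coordinates (0.2 s window) by
central differences, one-sided at the ends; tracking dropouts up to
0.4 s are bridged by linear interpolation, longer gaps stay invalid and
propagate. Epoch restriction uses half-open intervals `[start, end)`.

## Oscillations

**Filtering.** All band-pass filters are 4th-order Butterworth applied
forward and backward (`sosfiltfilt`), i.e. zero-phase. The first and
last ~0.5 s of a filtered trace carry edge transients; tests exclude
these margins when checking phase accuracy.

**SWR detection.** Ripple-band (125–250 Hz) RMS in 20 ms windows
stepped by 10 ms. Windows above mean + 7 SD seed an epoch, which
extends in both directions while windows stay above mean + 2.5 SD.
Epochs closer than 10 ms are merged; epochs shorter than 20 ms are
dropped; epochs whose seed coincides (±20 ms) with a 7 SD excursion on
the reference channel are rejected as artifacts.

*Two-pass baseline.* With genuine events present at ~0.3/s, the naive
all-window mean/SD is inflated by the events themselves and the 7 SD
threshold misses a substantial fraction of true ripples. By default
the baseline mean/SD is therefore re-estimated after excluding
first-pass detections (±one window). The baseline statistics can also
be restricted to rest trials via `baseline_epochs`.

**SWR characterization.** Peak-power time is the highest RMS window
inside the epoch; ripple cycles are descending zero-crossings of the
band-filtered trace; amplitude is half the peak-to-trough excursion
within one ripple cycle of the peak. Peak frequency is the ripple-band
argmax of the epoch's spectrum.

*Single-taper peak frequency.* Averaged spectra use DPSS multitapers
with NW = 3, K = 5. For a single ~50 ms epoch that bank is flat over
±NW/T ≈ ±50 Hz and the argmax wanders tens of Hz, so per-epoch peak
frequency uses one concentrated taper (NW = 1.5, K = 1) with the FFT
zero-padded to ≥1024 points (grid refinement only; power is
conserved). Measured median carrier error drops from ~23 Hz to ~2 Hz.

**Multitaper PSD.** One-sided PSD averaged over DPSS tapers and
segments, scaled so that `sum(psd) * df` equals the signal variance
(Parseval); shorter segments are zero-padded to the longest.

**Morlet time-frequency maps.** Each wavelet has a temporal SD of one
period and unit total energy. Under this normalization the expected
energy per frequency row is flat for white noise, while the ridge
response to a unit-amplitude tone scales as f^(−1/2); both properties
are tested. Default grid 90–300 Hz in 2 Hz steps; SWR-triggered maps
average ±125 ms around peak power.

**Theta.** Theta epochs are consecutive non-overlapping 500 ms windows
with theta (6–10 Hz) to delta (2–4 Hz) RMS ratio above 2, merged when
contiguous. Theta phase is defined on the 5–14 Hz filtered trace: 0°
at descending (positive-to-negative) zero-crossings, advancing
linearly to 360° at the next crossing. The `PhaseSeries` keeps the
crossing times per epoch so spike phases are interpolated from the
crossings exactly, not resampled. Ripple phase uses the same
construction with ripple cycles inside SWR epochs.

## Unit classification (`units`)

Three features per unit: log10 mean firing rate over the session, the
count-weighted first moment (ms) of the spike-train autocorrelation up
to 25 ms in 0.5 ms bins, and spike duration (ms) at 25% of the
waveform's peak magnitude with linearly interpolated crossings. A
pyramidal template (mean and covariance) is built from ≥4 reference
units — in the pipeline, units with spatial information > 0.5
bits/spike — with diagonal regularization if the covariance is
near-singular. Units with Mahalanobis distance < 20 are pyramidal,
> 40 interneurons, otherwise unclassified. Isolation distance is the
n-th smallest Mahalanobis distance of noise spikes from the cluster
(n = cluster size), reported as infinity when noise spikes are fewer
than cluster spikes; a squared variant is selectable.

## Spatial analysis (`spatial`)

Maps use 2 cm bins, samples with speed > 3 cm/s, and Gaussian
smoothing with 3 cm SD truncated at 3 SD. Smoothing conserves total
mass at arena edges by spreading each bin with a kernel renormalized
to its in-arena part (`conv(x / conv(1, K), K)`); total occupancy
therefore equals gated time exactly, and the edge bias cancels in the
rate ratio. The default rate map is smoothed counts over smoothed
occupancy (`ratio_of_smoothed`); smoothing the raw ratio is available
as `smoothed_ratio`. Bins with raw occupancy below 0.05 s count as
unvisited. Fields are detected iteratively: highest unassigned bin
above 5 Hz, flood-filled 4-connected down to 20% of that peak, kept if
≥10 bins (2D); the 1D variant extends along the line with no minimum
size. Skaggs spatial information Σ pᵢ(λᵢ/λ) log2(λᵢ/λ) (bits/spike)
and sparsity (Σ pᵢλᵢ)²/Σ pᵢλᵢ² are computed over visited bins;
selectivity scores are only reported for cells with ≥300 spikes in the
trial. Map stability is the Pearson correlation over common visited
bins (undefined below 10 common bins or zero variance).

The zigzag maze (five 65 × 7 cm alleys joined by semicircular turns)
is linearized by projecting positions onto the skeleton polyline with
a KD-tree; the 1D coordinate is arc length from the south end
(total ≈ 340.7 cm). Runs are segmented at visits to the two maze ends
(8 cm end zones) and labelled northbound/southbound; samples outside
complete end-to-end runs get direction 0.

## Phase coding (`phase`)

Mean resultant vector length R and circular mean come from the unit
resultant; the Rayleigh p-value uses the standard finite-n
approximation exp(−Z)(1 + (2Z − Z²)/(4n)), Z = nR², clamped to [0, 1].
Watson's two-sample U² is computed from the cumulative-fraction
formulation over the pooled sample and compared against tabulated
critical values (0.187 at α = 0.05, 0.268 at α = 0.01). Firing
probability per phase bin is spikes per bin per complete oscillation
cycle (12 bins). Burst theta frequency is 1000/t* where t* is the
first peak in 70–180 ms of the ±200 ms spike-train autocorrelation
(2 ms bins, 3-bin boxcar).

**Precession fit.** The slope a (cycles per field traversal, bounded
to ±2) maximizes the mean resultant length of θ − 2πax over a coarse
grid (step 0.02), with a fine local refinement (step 10⁻³) for the
reported slope. The signed correlation r is the circular-circular
(Jammalamadaka) correlation between observed phases and the fitted
line, with the slope's sign. Significance comes from permuting
positions against phases (default 1000 permutations in the API, 200 in
the pipeline) and recomputing the best coarse-grid resultant;
p = (1 + #{perm ≥ obs}) / (1 + n_perm). The coarse grid is used for
both the observed and permuted statistics so the permutation test is
exchangeable. A field shows significant precession when p < 0.05 and
r < 0.

## Synthetic sessions (`synthgen`)

The generator emulates the statistical structure the analyses assume —
it is calibration plumbing, not a biophysical model, and none of its
parameters are claims about any particular dataset.

- **Trajectories** (25 Hz): open-field foraging is an
  Ornstein–Uhlenbeck velocity walk (mean speed ~12 cm/s, reflecting
  walls) covering ≥90% of 2 cm bins in 20 min; rest is slow jitter in
  a 23 × 25 cm box (≥95% of samples below 3 cm/s); the zigzag arena
  produces end-to-end skeleton runs at 12–18 cm/s with 1.5–4 s pauses.
- **LFP** (1 kHz): pink (1/f) background noise, plus speed-gated theta
  with wandering instantaneous frequency (6.2–9.8 Hz), plus ripple
  bursts (Gaussian envelope SD 10 ms, carrier uniform 130–180 Hz)
  injected at Poisson times (default 0.3/s) during immobility with
  amplitude 8× the ripple-band noise SD. The default SNR puts the 7 SD
  threshold on the operating curve's shoulder, so detection is a
  meaningful test rather than a triviality. The reference channel
  shares the background but carries no ripples.
- **Spikes**: inhomogeneous Poisson trains by exact thinning. Place
  cells: Gaussian spatial envelope × von Mises theta modulation
  (normalized to unit mean over the cycle) whose preferred phase
  shifts linearly with relative field position by the precession
  slope × SWR gain inside SWR intervals. 1D fields on the zigzag are
  direction-gated: the envelope is zero when running opposite the
  cell's preferred direction. Interneurons are tonic with theta and
  ripple-phase modulation.
- **Unit features and waveforms**: feature vectors are drawn from two
  separated clusters (wide, slow pyramidal cells vs narrow, fast
  interneurons) whose separation mimics the template-distance regime
  implied by the 20/40 thresholds; waveform widths are calibrated so
  the measured 25% duration matches the drawn feature.
- **Sessions**: nine trials (rest / open field / rest / zigzag,
  alternating, default 20 min each), deterministic given the seed.

## Pipeline (`pipeline`)

`run_session` executes SWR detection (baseline statistics from rest
trials), theta epochs/phase, unit features and classification
(template from units with spatial information > 0.5 in the first
open-field trial), open-field selectivity, theta and ripple phase
locking (theta-modulated at Rayleigh p < 0.01), and precession on the
first zigzag trial for both run directions. Any stage error is
recorded by name and dependent stages are skipped. Outputs are seven
CSV tables written with `%.10g`; reruns are byte-identical.
`compare_groups` uses the rank-sum test (normal approximation, tie
corrected) for linear metrics and Watson's U² for circular ones; the
unit of analysis (cell vs session/mouse aggregate) is chosen by the
caller when assembling the input arrays. No multiple-testing
correction is applied.

## Limitations

- The precession permutation test reports p ≥ 1/(1 + n_perm); with the
  pipeline's 200 permutations the smallest attainable p is ~0.005.
- The generator's parameter defaults define the simulated study
  conditions; they were fixed before the recovery experiments and are
  not tuned to any acceptance outcome.
- Morlet ridge magnitudes are frequency-dependent (∝ f^(−1/2)) under
  the unit-total-energy normalization; comparisons across frequencies
  should use the white-noise-flat energy property, not raw ridge
  heights.
- Theta phase is undefined (NaN) outside detected theta epochs and
  near filter edges; spikes there are dropped from phase analyses and
  counted.
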
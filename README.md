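# hippocode

Analysis of hippocampal CA1 tetrode recordings: sharp wave/ripple (SWR)
detection and characterization in the local field potential, theta
oscillations and theta phase, classification of units into pyramidal
cells and interneurons, place fields and spatial selectivity, and theta
phase coding including phase precession. A synthetic-session generator
with full ground truth makes every stage testable by recovery.

## Science

During immobility and sleep, CA1 produces sharp wave/ripples — brief
(tens of ms) 125–250 Hz oscillations riding on sharp waves — while
locomotion is dominated by 6–10 Hz theta. `hippocode` implements the
standard analysis chain for such recordings:

- **SWRs**: ripple-band power (zero-phase Butterworth, RMS in 20 ms
  windows stepped by 10 ms) thresholded at 7 SD above the mean and
  extended to 2.5 SD, with artifact rejection against a reference
  channel outside the pyramidal layer; per-event duration, amplitude,
  ripple-cycle times and multitaper peak frequency.
- **Theta**: epochs where the theta/delta RMS ratio exceeds 2 in 500 ms
  windows; phase defined as 0° at descending zero-crossings of the
  5–14 Hz filtered trace and interpolated linearly between crossings;
  Morlet-wavelet time-frequency maps and DPSS multitaper spectra.
- **Units**: classification into pyramidal cells and interneurons by
  Mahalanobis distance to a template built from reference place cells,
  using firing rate, the first moment of the ≤25 ms spike-train
  autocorrelation, and spike duration at 25% amplitude; isolation
  distance as the cluster-quality metric.
- **Space**: occupancy-normalized rate maps (2 cm bins, 3 cm Gaussian,
  samples above 3 cm/s), place-field detection by iterative
  peak-and-extend flood fill, Skaggs spatial information, sparsity, and
  map stability; linearization of a five-alley zigzag maze with
  per-run direction labels.
- **Phase coding**: spike-phase assignment by interpolation between
  oscillation cycles, mean resultant vector length with the Rayleigh
  test, Watson's two-sample U² for phase-distribution comparisons, and
  phase precession by circular-linear fit (slope maximizing the
  resultant of phase residuals; significance by permutation).
- **Statistics**: Wilcoxon rank-sum (normal approximation with tie
  correction) for group comparisons of linear metrics, Watson U² for
  circular ones.

## Worked example

Detect ripples injected into a synthetic ten-minute rest recording
(`examples/detect_ripples.py`):

```sh
$ python examples/detect_ripples.py
injected 179 ripples (carriers 131-180 Hz)
detected 179 SWR epochs (0.30/s)
duration: median 50 ms
peak frequency: median 156.2 Hz
recall 1.000
```

Fit theta phase precession on a synthetic place field
(`examples/phase_precession.py`):

```sh
$ python examples/phase_precession.py
precessing field: slope -1.04 cycles/field, r = -0.765, p = 0.0010
significant precession: True
control field:    slope -0.00 cycles/field, r = -0.007, p = 0.9001
significant precession: False
```

Or run everything on a full nine-trial session
(`examples/full_session.py`; ~1 min):

```sh
$ python examples/full_session.py
...
16/16 units correctly classified
precession: 12/20 fields significant (negative circular-linear r, p < 0.05)
```

The other examples cover theta phase locking
(`theta_phase_locking.py`) and place-field selectivity
(`place_fields.py`).

## Command line

```sh
hippocode simulate --seed 42 --out session/      # synthetic session + ground truth
hippocode validate session/                      # data-model checks
hippocode run session/ --out results/            # full chain -> CSV tables
hippocode swr session/ --out swr.csv             # individual stages
hippocode theta session/
hippocode phase session/ --oscillation theta
hippocode precession session/
hippocode compare results_a/ results_b/ --metric vector_length --table theta_phase
```

`hippocode run` writes `swr.csv`, `theta_epochs.csv`, `units.csv`,
`selectivity.csv`, `theta_phase.csv`, `ripple_phase.csv` and
`precession.csv`; reruns on the same inputs are byte-identical.

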
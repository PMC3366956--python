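"""Place fields, spatial information and sparsity in the open field.

Simulates foraging with a place cell, builds the smoothed rate map
(2 cm bins, 3 cm Gaussian, speed > 3 cm/s), detects the field by
iterative peak-and-extend flood fill, and scores spatial selectivity.
"""

import numpy as np

from hippocode.session_io import compute_speed
from hippocode.spatial import detect_fields_2d, rate_map, sparsity, spatial_information
from hippocode.synthgen import PlaceCellTuning, analytic_phase_series, gen_place_cell, gen_trajectory

track = gen_trajectory("open_field", duration=1200.0, seed=6)
speed = compute_speed(track)

tuning = PlaceCellTuning(
    peak_rate=12.0, field_center=(30.0, 45.0), field_sd=6.0, theta_kappa=1.0
)
phase = analytic_phase_series(8.0, 1200.0)
spikes = gen_place_cell(track, phase, tuning, seed=7)
print(f"place cell fired {spikes.size} spikes in 20 min")

rm = rate_map(spikes, track, speed, arena=(70.0, 70.0))
print(f"rate map: {rm.rate_hz.shape[0]}x{rm.rate_hz.shape[1]} bins, "
      f"peak {rm.rate_hz.max():.1f} Hz, {rm.visited.mean() * 100:.0f}% bins visited")

fields = detect_fields_2d(rm)
for f in fields:
    cx, cy = f.centroid(rm)
    print(f"field: {f.n_bins} bins ({f.size:.0f} cm^2), "
          f"peak {f.peak_rate:.1f} Hz, centroid ({cx:.0f}, {cy:.0f}) cm")

info = spatial_information(rm)
sp = sparsity(rm)
print(f"spatial information {info:.2f} bits/spike, sparsity {sp:.2f}")
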
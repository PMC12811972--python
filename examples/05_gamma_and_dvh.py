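"""Comparison machinery: 3D gamma index, dose-difference histogram, DVH.

Compares the default plan's dose grid against a noisy simulated reference
(standing in for an independent transport calculation).
"""

import numpy as np

from brachyaudit import compare, phantom, tg43
from brachyaudit.uncertainty import derive_criteria, load_budget

geom = phantom.build_default_phantom(seed=0)
plan = phantom.build_plan(geom)
origin, spacing, dims = [-40.0, -20.0, -40.0], [2.0, 2.0, 2.0], (41, 21, 41)
tps = tg43.accumulate_dose(plan, origin, spacing, dims)
ref = phantom.simulate_reference_dose(plan, origin, spacing, dims, noise_rel=0.01, seed=7)

dd, dta = derive_criteria(load_budget("film"))
crit = compare.GammaCriteria(dd, dta, mode="local", low_cutoff_gy=1.5)
res = compare.gamma_map(ref, tps, crit)
print(f"local gamma {dd}%/{dta} mm (1.5 Gy cutoff): {res.summary}")

diff = compare.local_diff_map(ref, tps)
stats = compare.diff_histogram(diff, ref, low_cutoff_gy=1.5, high_cutoff_gy=24.0)
lo, hi = stats.percentile_range_pct
print(f"local dose differences over {stats.n} voxels: median {stats.median_pct:+.2f}% "
      f"[{lo:+.2f}%, {hi:+.2f}%]")
# median ~0: the reference here is the same engine plus 1% noise

masks = phantom.structure_masks(geom, tps)
for name, mask in masks.items():
    dvh = compare.compute_dvh(tps, mask, name)
    print(f"{name}: Dmean {dvh.d_mean_gy:.2f} Gy, D90 {dvh.d90_gy:.2f} Gy, "
          f"Dmax {dvh.d_max_gy:.2f} Gy over {dvh.voxel_count} voxels")
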
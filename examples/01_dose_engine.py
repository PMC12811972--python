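"""TG43 dose engine: single-dwell dose rates, TRAK and decay correction.

Builds a single dwell of the bundled generic Ir-192 line source and probes
the dose rate at reference geometry, then shows plan-level quantities.
"""

import numpy as np

from brachyaudit import tg43

source = tg43.load_default_source()  # Sk = 12765.5 U, Lambda = 1.109 cGy/(h U)
dwell = tg43.DwellPosition(center_mm=[0, 0, 0], axis_direction=[0, 0, 1], dwell_time_s=60.0)

rate_ref = tg43.dose_rate(source, dwell, np.array([10.0, 0.0, 0.0]))
print(f"dose rate at r = 1 cm, theta = 90 deg: {rate_ref:.1f} cGy/h "
      f"(= Sk*Lambda = {source.air_kerma_strength * source.dose_rate_constant:.1f})")

for r_mm in (10, 20, 50):
    rate = tg43.dose_rate(source, dwell, np.array([float(r_mm), 0.0, 0.0]))
    print(f"  r = {r_mm:3d} mm: {rate:9.1f} cGy/h")
# falls roughly with inverse square, softened by g(r) and the line geometry

plan = tg43.Plan({1: [dwell]}, source)
print(f"TRAK of a 60 s dwell: {tg43.trak(plan):.2f} U*h")
print(f"Sk after one half-life: {tg43.decay_correct(source.air_kerma_strength, 73.83):.1f} U")
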
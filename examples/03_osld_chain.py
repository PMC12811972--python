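"""OSLD dose determination: session calibration, correction chain, k_vol.

Simulates a calibration session and noisy chip readouts for the default
plan, then recovers dose to water through the multiplicative chain.
"""

import numpy as np

from brachyaudit import osld, phantom

geom = phantom.build_default_phantom(seed=0)
plan = phantom.build_plan(geom)

# session calibration: nine standards at 0.5 Gy in the 6 MV reference field
nd_true = 2.5e-3
rng = np.random.default_rng(1)
standards = [osld.OSLDReadout(f"std{i}", 0.5 / nd_true * (1 + rng.normal(0, 0.015)))
             for i in range(9)]
session = osld.session_calibration(osld.CalibrationSession(standards))
print(f"N_D = {session.nd_gy_per_count:.4e} Gy/count "
      f"(type A {session.type_a_unc_pct:.2f}%)")

# simulate readouts with the pilot beam-quality factor and 1% reader noise
truth = {s.chip_id: osld.CorrectionFactors(kQ=osld.DEFAULT_KQ) for s in geom.osld_sockets}
readouts = phantom.simulate_osld_readouts(plan, geom, truth, nd_true, noise_rel=0.01, seed=2)

print("chip      kvol   D_w (Gy)  truth (Gy)")
for (_, row), socket in zip(readouts.iterrows(), geom.osld_sockets):
    kvol = osld.compute_kvol(plan, socket.center_mm)
    factors = osld.CorrectionFactors(kQ=osld.DEFAULT_KQ,
                                     kQ_unc_pct=osld.DEFAULT_KQ_UNCERTAINTY_PCT).with_kvol(kvol)
    dw, unc = osld.dose_from_readout(
        osld.OSLDReadout(row["chip_id"], row["signal"]), session.nd_gy_per_count, factors
    )
    print(f"{row['chip_id']}  {kvol:.4f}  {dw:8.3f}  {row['true_mean_dose_gy'] * kvol:9.3f}")
# recovered doses track the true centroid doses within the ~1-2% noise floor
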
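# brachyaudit

An end-to-end **remote dosimetry audit toolkit for Ir-192 HDR interstitial
brachytherapy**, written for medical physicists who develop or evaluate
postal audit programs. It models the complete hybrid workflow around a
compact RW3 slab phantom: a TG43 dose engine and two-catheter treatment
plan, ten BeO OSLD point measurements, two radiochromic-film planes
registered to the planning CT via metal-pin fiducials, and an independent
computational (transport-reference) comparison — all exercisable with no
physical measurements through a synthetic-data factory.

## The model

Dose around the stepping source follows the AAPM TG43 2D formalism,

```
Ḋ(r, θ) = S_K · Λ · [G_L(r, θ) / G_L(1 cm, 90°)] · g(r) · F(r, θ)
```

with a line-source geometry function, tabulated radial dose and anisotropy
functions, and multi-dwell superposition (dose in Gy = Σ Ḋ·t/3600/100).
OSLD dose to water applies the correction chain
`D_w = M_Q · N_D,w,Qref · k_s,i · k_L · k_Q · k_θ · k_f · k_vol`, with the
session calibration from nine standard chips, the beam-quality factor
k_Q = 1.06 ± 2.5% for the primary Ir-192 spectrum, and a plan-specific
volume-averaging correction k_vol computed by quadrature over the chip's
active volume. Film dose comes from a per-channel netOD power-law
calibration (`d = p₁x + p₂x^p₃`) with inverse-variance channel combination,
then a closed-form rigid 2D/3D registration from three pin-hole/pin-centroid
fiducial pairs. Comparisons use the 3D gamma index (local and global), with
the passing criteria *derived* from quadrature uncertainty budgets
(OSL: 4.4% / 0.8 mm at k = 1 → 5%/1 mm; film: 3.8% / 1.6 mm → 4%/2 mm),
plus local dose-difference histograms (1% bins, 1.5 / 24 Gy cutoffs) and
DVH comparison.

See `docs/methods.md` for assumptions, the measurement error model, and
numerical conventions.

## Worked example

```python
from brachyaudit import phantom, tg43, osld
from brachyaudit.uncertainty import load_budget, derive_criteria

geom = phantom.build_default_phantom(seed=0)
plan = phantom.build_plan(geom)           # 36 dwells, 2 mm step, 3 Gy
doses = tg43.dose_at_points(plan, plan.prescription_points_mm)
print(len(plan.dwells), round(plan.total_time_s, 1), round(doses.mean(), 3))
kv = [osld.compute_kvol(plan, s.center_mm) for s in geom.osld_sockets]
print(round(min(kv), 3), round(max(kv), 3))
print(derive_criteria(load_budget("osl")), derive_criteria(load_budget("film")))
```

prints

```
36 433.9 3.0
0.985 0.994
(5, 1) (4, 2)
```

— a 36-dwell plan delivering a mean of exactly 3 Gy to the mid-axis
prescription points in 433.9 s; volume-averaging corrections between 0.985
and 0.994 across the ten chips (sub-percent corrections, as expected 12–20 mm
from the catheters); and gamma criteria of 5%/1 mm (OSLD) and 4%/2 mm (film)
derived from the uncertainty budgets.

A full synthetic audit, plus the same audit with a deliberate 2 mm
catheter-tip reconstruction error:

```bash
brachyaudit audit --seed 1 --report scratch/free.json
brachyaudit audit --seed 1 --shift 2.0 --report scratch/shifted.json
brachyaudit report scratch/shifted.json
```

The error-free run passes every branch (OSLD global gamma 10 of 10, film
pass rates 100%). The shifted run drops the OSLD counts to 8 of 10 and
produces film gamma failures, while the computational branch — which only
ever sees the exported plan — is bit-identical: the signature of a delivery
error that a purely computational audit cannot catch.

`examples/` contains one short narrative script per capability (dose
engine, synthetic data, OSLD chain, film registration, gamma comparison,
full audit).

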
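# Methods

`brachyaudit` implements a complete remote (postal) dosimetry audit for
Ir-192 HDR interstitial brachytherapy as software: a TG43 dose engine and
plan model, a digital twin of the audit phantom with generators for every
raw data stream the physical workflow produces, the OSLD and radiochromic
film analysis pipelines, the comparison machinery (3D gamma index, local
dose differences, DVHs), and the uncertainty bookkeeping that fixes the
passing criteria. This note records the models, the parameter choices, and
what the synthetic data do and do not establish.

## Dose engine

The engine evaluates the AAPM TG43 2D line-source formalism,

D&#775;(r, θ) = S_K · Λ · [G_L(r, θ) / G_L(1 cm, 90°)] · g(r) · F(r, θ),

with the geometry function G_L = β/(L·r·sinθ) off axis, 1/(r² − L²/4) on
axis (the off-axis branch hands over to the closed form below sinθ = 10⁻³,
where the two agree to better than 10⁻⁶ relative), and the point-source
limit 1/r² for L → 0. g(r) is interpolated linearly in r and F(r, θ)
bilinearly in (r, θ), with the table mirrored about 90°.

The bundled source data (`data/ir192_radial_dose.csv`,
`data/ir192_anisotropy.csv`) describe a *generic* Ir-192 line source with
L = 3.5 mm and Λ = 1.109 cGy·h⁻¹·U⁻¹ — class values, shipped as editable
configuration rather than code, because vendor-specific consensus tables are
not redistributed here. Consequently no quantitative agreement with any
vendor-specific published dose map is claimed; every test that needs
absolute dose consistency uses the engine itself on both sides or an
independent re-implementation of the same formalism (quadrature of the line
integral plus separately coded interpolators).

Units: the TG43 core works in cm and hours (S_K in U = cGy·cm²·h⁻¹); all
public geometry is mm in the DICOM patient frame, dwell times are seconds,
accumulated dose is Gy. Conversions happen once, at the module boundary.
The Ir-192 half life is 73.83 d. Field points within 1 mm of a dwell
centre are flagged "near-source"; their values come from a radius clamped
to the table minimum and are excluded from comparisons, mirroring the
near-source unreliability a TPS handles with its 800% dose threshold.

## Digital phantom and plan

The phantom is six 1-cm RW3 slabs (9.5 × 10 × 6 cm³, ρ = 1.04 g·cm⁻³) with
two parallel catheters 4 cm apart on the mid-plane, ten BeO chips
(4.65 × 4.65 × 0.5 mm³) on the catheter plane at 12 or 20 mm from the
nearer catheter, two film planes at ±10 mm, and three metal pins per film.
The exact chip pattern is not fully constrained by the protocol's phantom
description; the default layout places two symmetric rows per side
(inner chips between the catheters at 12 mm, outer chips outboard at
20 mm), point-symmetric about the centroid with ≥14 mm pitch, and is
configurable. Pin positions are drawn per-seed near the film edges,
rejecting triangles that are small, near-isosceles (pairwise side
differences must exceed 6 mm) or short-sided, so the fiducial
correspondence is always well posed.

The plan enables 18 dwells per catheter at a 2 mm step over a 3.4 cm
treatment length and prescribes 3 Gy to mid-axis points, one opposite each
dwell pair at 20 mm from both catheters. Dwell times are solved by bounded
nonnegative least squares with the times confined to a 3× modulation band
around the uniform loading and the result renormalized so the *mean*
prescription-point dose is exactly 3 Gy. Two properties motivated this
choice. First, the point system is severely ill-conditioned (the per-dwell
kernels at 20 mm are nearly collinear; an exact fit needs ±1800 s negative
times), so "3 Gy at every point" is only approximable: the solver contract
is a maximum per-point deviation of 15%, with ~12% realized at the tip
points. Second, an unconstrained nonnegative solution is extremely
edge-weighted (23× modulation), which flattens the longitudinal dose
falloff at the dwell tips and with it the dose signature of a catheter-tip
reconstruction error; the 3× band mirrors the mild modulation a clinical
distance optimizer produces (dwell times 6.7–20.0 s, total ≈ 434 s) and
keeps the deliberate low-dose (~55%) / high-dose (~137%) measurement areas
of the audit design.

The synthetic CT voxelizes the phantom at 0.27 × 0.27 × 0.6 mm³ with
RW3 ≈ 35 HU, chips 2000 HU, pins 3000 HU, air channels −1000 HU and
additive Gaussian noise (σ = 20 HU). HU values are chosen only to give
cleanly separable thresholds; no scanner physics (beam hardening, partial
volume beyond binary voxelization) is modelled. Chip localization
thresholds at 1000 HU and separates chips from pins by component volume
(bounds 4.5–25 mm³; a chip occupies ≥5 mm³, a pin ≤4 mm³ by construction).

## Measurement simulation and the error model

The generators emulate the *delivered* measurement chain, which differs
from the TPS's picture of it. Magnitudes follow the audit's uncertainty
budget; draws are truncated at 2σ (gross errors would be caught by QA):

* shared delivery-chain dose scale, σ = 1.5% (source strength plus
  reference-dosimetry chain);
* per-catheter reconstruction offset along the catheter, σ = 0.6 mm (one
  CT slice);
* OSLD: shared batch linearity error σ = 1.7%, shared beam-quality error
  σ = 2.0% (truncated at 1.5σ — part of the 2.5% budget entry is the side
  study's type-A spread, not a bias), per-chip sensitivity σ = 0.7% and
  orientation σ = 1.4%, multiplicative readout noise 1%;
* film: shared calibration-chain error σ = 2% (the 3.5% budget entry is a
  dose-dependent *bound*; observed error-free film pass rates of 96–99%
  imply actual errors of 1–2% in the >1.5 Gy range), per-pixel noise 1%,
  and a 0.3 mm "tear" offset of each punched pin hole from its pin centre —
  the dominant registration-error source the budget's 1.5 mm registration
  entry accounts for.

OSLD signals respond to the volume-mean dose over the chip:
M = D̄/(N_D·k_s,i·k_L·k_Q·k_θ·k_f); the analysis later multiplies by the
plan-specific k_vol to report the centroid dose. The deliberate 2 mm
catheter-tip shift moves the delivered field (both catheters, along the
catheter axis) relative to the planned one; the computational branch only
ever sees the exported plan and is provably unaffected.

What the synthetic data do *not* emulate: scanner lateral response, film
darkening kinetics (calibration and measurement are assumed scanned at the
same post-irradiation time), OSLD fading curves, catheter curvature, CT
beam hardening, and any real TG43-vs-transport discrepancy (the simulated
external reference is the engine dose plus 1% voxel noise, so the
computational branch's expected median difference is ≈ 0%, not the few
percent a transport calculation would reveal against TG43 in a finite
phantom). Passing tests therefore validate the *pipelines and their error
propagation*, not the physics fidelity of any TPS.

## OSLD pipeline

Dose to water follows the multiplicative chain
D_w = M_Q · N_D,w,Qref · k_s,i · k_L · k_Q · k_θ · k_f · k_vol. The session
calibration coefficient is N_D = D_ref / mean(M·k_s,i) over nine standards
irradiated to 0.5 Gy in the 6 MV reference field; its type-A uncertainty is
the relative standard error of that mean (the "one standard deviation of
the mean response" entry is read as the SEM). Whether the session mean
should use sensitivity-corrected or raw signals is not fully specified in
the protocol; the corrected mean is used. k_Q for the primary Ir-192
spectrum defaults to the pilot value 1.06 ± 2.5% and can be recomputed from
a side study as a ratio of calibration coefficients with the four component
uncertainties combined in quadrature. k_L, k_s,i come from batch
characterization files (identity defaults); k_f = k_θ = 1 under matched
conditions, with their uncertainties carried in the budget.

k_vol is the centroid dose over the volume-mean dose of the active volume,
computed with the analytic engine in a homogeneous geometry (independent of
the CT-based branch). The centroid dose is evaluated exactly at the point —
an analytic engine needs no finite scoring voxel — and the volume mean by
tensor-product midpoint quadrature, n doubled from 4 until successive
estimates agree within 10⁻⁴ (a quadratic field of curvature a over
half-width w has the closed form k_vol = 1/(1 + a·w²/3), which the
quadrature matches to 10⁻⁴). For the default plan all ten chips fall in
0.983–0.995, within the 0.95–1.10 band expected for this phantom and plan
class.

## Film pipeline

A generic Devic-style per-channel calibration replaces the proprietary
multi-gaussian triple-channel model of the original analysis software:
dose = p₁·netOD + p₂·netOD^p₃ per channel, fitted to a 12-piece 0–14 Gy
design (an unirradiated piece supplies the zero-light reference;
pre-irradiation scans are not required). Scan-to-dose conversion inverts
each channel and combines the three estimates with inverse-variance weights
derived from the channel sensitivities at the local netOD; pixels below the
1.5 Gy cutoff are flagged but retained. Pin holes transmit the full
scanner backlight, so hole detection is bright-disk: threshold at 0.85 of
the image maximum (scale-invariant), area-filtered components,
intensity-weighted sub-pixel centroids. Pins in CT are components above
2500 HU within 2 mm of the film plane.

Registration resolves the 3-point correspondence by matching pairwise
distance patterns (the audit uses a 2.5 mm tolerance to accommodate torn
holes; the pure-geometry default is 0.5 mm), decides the scan-face flip
from the triangle orientations (pairwise distances cannot), and fits the
in-plane rotation/translation in closed form (2D Kabsch). The fiducial
registration error (FRE) is the RMS residual; ~0.3 mm is typical with the
default tear model. Near-isosceles triangles raise an ambiguity error
listing both hypotheses rather than guessing.

## Comparisons

The gamma index uses an isotropic search lattice with step ≤ DTA/10
(default DTA/10, i.e. 0.1 mm at 1 mm DTA) within a search radius of 3·DTA,
trilinear interpolation of the evaluated grid, and a distance-sorted early
exit that provably returns the exhaustive lattice minimum (an offset is
only skipped once its distance term alone exceeds the current best gamma);
equality with an unpruned brute-force search is asserted exactly in the
tests. Measurements are always the reference; γ ≤ 1 passes, including the
boundary. Local mode normalizes the dose difference by the local reference
dose; global mode by a fixed normalization dose, which the protocol leaves
unstated — the default is the prescription dose (3 Gy), logged per run.
Point-mode results are reported as "k out of n" alongside percentages.

Local dose differences are (D_eval − D_ref)/D_ref × 100% with the evaluated
grid interpolated to the reference lattice; histograms use 1%-wide bins and
report the median and [2.5th, 97.5th] percentile range, after a 1.5 Gy low
and 24 Gy (800% of prescription) high cutoff on the reference dose. DVHs
are cumulative volume-percent curves with D_mean, D90, D_max; structures
are generated as label volumes from the phantom geometry (a high-dose
region between the catheters over the dwell span, two low-dose regions
beyond the tips). In-plane block-mean downsampling (0.27 → 0.54 mm,
slice thickness kept) conserves the dose-volume integral.

## Uncertainty budgets and criteria

Component lists ship as CSV mirroring the protocol budget (type A/B kept
as metadata; both enter one quadrature). OSL: 4.4% / 0.8 mm at k = 1;
film: 3.8% / 1.6 mm; displayed k = 2 values double the displayed k = 1
values (8.8% / 1.6 mm and 7.6% / 3.2 mm), matching the table convention.
Bound-type entries (the "<2.5%" stochastic-reference statistics) are stored
but excluded from quadrature. Gamma criteria are *derived*, not chosen:
the k = 1 totals rounded up to whole percent / mm give 5%/1 mm (OSL) and
4%/2 mm (film). The upward-rounding rule is an inference from those two
printed pairs and is configurable.

## The audit and what "detection" looks like at desk scale

`run_audit` executes all three branches for one seed: OSLD (session
calibration → correction chain → point gamma at 5%/1 mm, local and global),
film (calibration → dose maps → fiducial registration → gamma at 4%/2 mm
with the 1.5 Gy cutoff, per plane), computational (simulated external
reference vs TPS grid → difference histogram and DVH metrics). Default
problem sizes keep a full two-scenario audit around a minute: TPS and
reference grids at 1 mm (95 × 60 × 100 voxels), film comparison lattices at
1 mm on each film plane (~4900 points), film scans rendered at the full
0.17 mm scan pitch, CT at the full 0.27 × 0.27 × 0.6 mm resolution.

Error-free runs pass: OSLD global gamma 10/10 and film rates above 95%
across seeds (occasionally 9/10 on the tighter local/global tests, exactly
as a budget-consistent error draw predicts). Under the deliberate 2 mm
shift the OSLD pass counts drop to 5–8 of 10 and film failures appear
(rates typically 93–99%), while the computational branch is bit-identical.
The film drop is structurally milder than the experimental pilot's reported
83%: a parallel shift of both catheters translates the delivered field
almost rigidly, and a 2 mm translation against a 2 mm DTA criterion sits on
the γ = 1 boundary — only measurement systematics and noise push boundary
pixels into failure. The OSLD criterion (1 mm DTA) resolves the shift
robustly. Branch verdicts use configurable action levels (all OSLDs pass
globally; film ≥ 90%; |median computational difference| ≤ 5%).

## Numerical and degenerate-input conventions

Beyond-table radii raise a range error unless inverse-square-times-last-g
extrapolation is enabled (off by default); radii below the table are
clamped only for flagged near-source points. Zero dwell times, empty
plans, empty structure masks, sub-cutoff comparisons and non-invertible
calibrations raise or warn explicitly rather than returning silent zeros.
All generators are bit-reproducible for a fixed seed, and an audit report
embeds the seed, criteria, cutoffs, normalization dose and package version
needed to re-execute it; identical configuration yields a byte-identical
report.
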
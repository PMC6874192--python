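# Methods

This note documents the models implemented in `protoscatter`, the
choices made where the design was genuinely open, and what the synthetic
phantoms do and do not emulate.

## Scatter-factor workflow

For one field the pipeline computes three point doses with an identical
beam (source position, SOBP weights, beamlet lattice, air gap):

1. `d_p/c` — in the patient phantom with the compensator;
2. `d_vp/c` — in a homogeneous water phantom with the compensator, at a
   point on the central axis whose geometric depth equals the patient's
   water-equivalent depth (WED), matched within 0.1 mm water;
3. `d_vp/nc` — same point, compensator removed (beam energy and weights
   unchanged — the compensator is removed, not compensated for).

`PSF = d_p/c ÷ d_vp/c`, `CSF = d_vp/c ÷ d_vp/nc`, `CPSF = PSF × CSF`.
The water phantom keeps the patient grid's entrance plane, lateral
extent and spacing, so the aperture-to-skin distance is preserved; the
grid is deepened automatically when the patient WED exceeds it. The
calculation point defaults to the target centroid (the isocentre
surrogate, mid-SOBP); `axial_dose_gradient` and the scenario runner's
`point_shift_mm` expose the sensitivity of factors to points sitting in
a dose-gradient region, but no behaviour is asserted about it.

Because all three doses share one code path, two identities hold to
machine precision and are enforced by tests: a water "patient" gives
PSF = 1, and a zero-thickness compensator gives CSF = 1 bit-exactly.

## Pencil-beam engine

A field is a fan of beamlets from a point source at SAD = 200 cm (the
true machine value is not public; any value ≫ range works) on a square
lattice (default 2 mm at isocentre) clipped to a circular aperture.
Beamlet *b* contributes to point *p*:

    w_sobp(ζ_b) · G2(r_b; σ_b) · (SAD/L_b)² · ΔA

- ζ_b: compensator water-equivalent thickness plus patient WED along
  *b* to *p*'s axial plane. WED uses exact voxel-boundary ray traversal
  (verified against a 0.02 mm midpoint-integration oracle to ≤ 0.5%,
  typically ≤ 0.11%).
- w_sobp: the spread-out Bragg peak, a non-negative least-squares fit of
  Bortfeld-model pristine curves to a flat plateau over [R−M, R−0.1 cm].
  The pristine curve is the analytic Bragg-Kleeman/Bortfeld shape
  (α = 0.0022 cm·MeV^−1.77, p = 1.77, straggling σ = 0.012·R^0.935 cm,
  β = 0.012 cm⁻¹, γ = 0.6, ε = 0.1), tabulated once per range. Two
  numerical choices matter and were set after measuring alternatives:
  (a) a simpler plateau-plus-Gaussian peak cannot produce a plateau flat
  to ±2% down to R−0.1 — its distal shape is not representable by any
  non-negative weight combination — so the full analytic model is used;
  (b) all pristine ranges carry a uniform calibration offset placing the
  deepest peak's maximum at the nominal R, since clinically R denotes
  the distal edge of the flat region, not the raw range parameter.
  Default peak spacing is 1.2 straggling widths (plateau ripple ≈ ±1%).
- σ_b²: source spot size (default 4 mm) plus Highland multiple-
  scattering widths, θ0 = (14.1 MeV/pv)·√(x/X0)·(1 + log10(x/X0)/9),
  accumulated separately for the compensator (PMMA, X0 = 34.1 cm,
  drifted over half its thickness plus air gap plus depth) and the
  patient (cumulative x/X0 from the calibration, drifted over half the
  material path). This is a single-θ0 drift per medium, not Fermi-Eyges
  transport: adequate for the ratio physics, not for penumbra modelling.
- Inverse square per beamlet from the point source.

Doses are in arbitrary engine units; only ratios are meaningful. The
engine is linear in the SOBP weights (exact), symmetric under lateral
reflection, and self-consistent under lattice refinement to ≤ 0.5%.

What drives the factors in this model: at matched WED the depth-dose
term cancels (both points sit on the SOBP plateau), so the PSF is
carried by the *geometric* depth difference — air makes the patient
point geometrically deeper than the water point (smaller inverse-square
and longer drift), bone makes it shallower — while the CSF is carried by
the lateral variation of σ across the field: thick compensator regions
at the periphery scatter extra fluence toward the axis, so CSF ≥ 1 and
grows with thickness irregularity. These are the same mechanisms argued
physically for the real factors, minus nuclear halo and large-angle
tails, which is why the engine reproduces directions and approximate
magnitudes (lung PSF ≈ 0.92 at ~31% air; pelvis PSF ≈ 1.014 at ~4%
dense bone) but is not a dose algorithm.

## Materials

Five integer-HU classes partition [−1000, 1245] at edges −1000, −650,
−500, 125, 500, 1245 (upper edges inclusive; values clamp outside).
The HU→(RSP, density, 1/X0) calibration is piecewise linear through
seven knots chosen to reproduce the air/water/bone ordering of clinical
stoichiometric calibrations: (−1000, 0.001, 0.0012), (−650, 0.30, 0.30),
(−500, 0.45, 0.45), (0, 1.00, 1.00), (125, 1.07, 1.09),
(500, 1.28, 1.35), (1245, 1.60, 1.85), with relative inverse scattering
length = density × 1.7 for bone-class knots (higher effective Z). The
calibration is data, not code: a CSV with header `hu,rsp,density,inv_x0`
can replace it (`--calibration`), since the published variant used
clinically is not specified. Full stoichiometric tissue decomposition is
out of scope.

## Synthetic phantoms

All generators are deterministic under a fixed seed, emit int16 HU grids
(default 2 mm isotropic, 30 cm cube; half-voxel world convention:
voxel-centre = origin + (index+0.5)·spacing) and round-trip losslessly
through MetaImage.

Heterogeneity is laid down as full-cross-section bands along the beam
(+z) axis. This is deliberate, and two alternatives were rejected after
measurement: off-axis sphere pockets decouple the central-axis WED from
the beam's-eye-view (BEV) composition, which destroys the monotone
PSF-composition relationship the phantoms exist to probe (a lateral
bone block produces PSF = 1.00000 in this engine because Gaussian
beamlet tails at 3–5 cm are ~1e−8 — whereas a lateral prostate field
physically crosses the femoral head *on axis*). Bands also make the
requested composition exact: the achieved BEV fraction equals
`round(f·nz)/nz` (within ±0.7 pp at the coarsest grids used, well inside
the ±2 pp lung / ±1 pp pelvis tolerances).

- `make_lung_phantom(air_fraction ≤ 0.6, seed)`: soft-tissue body with a
  ~2 cm chest-wall shell, HU −800 air bands drawn from the interior
  slice set with the seeded generator, a central soft-tissue target kept
  clear of pockets, and an optional HU −1000 entrance gap slab
  (`surface_gap_mm`) emulating an immobilisation-device air gap (not
  counted toward the fraction and not asserted to reproduce any clinical
  geometry).
- `make_pelvis_phantom(dense_bone_fraction ≤ 0.10, seed)`: an HU 700
  dense-bone core wrapped in HU 300 cortical shell slices, placed with
  the seeded generator between entrance and target.
- `make_slab_phantom(layers)`: arbitrary axis-aligned slabs, the WED
  oracle geometry.

What passing tests on these phantoms show: the factor *mechanisms* and
their composition trends. What they do not show: behaviour under real
anatomy (lateral heterogeneity, curved surfaces, CT noise, motion),
absolute factor magnitudes for any specific patient, or pencil-beam
versus Monte Carlo discrepancies — the packaged study tables carry the
published numbers for those.

## Compensator laboratory

`design_compensator` traces a source ray per lateral position to the
deepest target voxel: t(x,y) = max(0, (R − WED_distal)/RSP_PMMA), with
RSP_PMMA = 1.16; rays missing the target take the maximum neighbouring
thickness (no other smearing). The closure t·RSP + WED_distal = R holds
within one voxel's water-equivalent thickness.

The irregularity metric is the IQR (linear interpolation of order
statistics — the common convention, stated because IQR shifts by
convention) of thickness within the *maximum scattering distance* of the
central axis. That distance has no published formula; it is defined here
as 3 projected Highland sigmas (99.7% containment) of the median
compensator thickness at the beam energy, drifted over air gap plus
depth, with a 0.1 cm thickness floor so flat maps keep a finite radius.
The 3σ containment choice is configurable; 1σ or 2σ simply rescale the
sampling disc.

## Empirical models and study tables

`fit_line`/`predict` are ordinary least squares of a factor against one
predictor (%air, %dense bone, or IQR). Coefficients are shipped only as
fitted data objects produced by this pipeline (JSON), never hard-coded;
a literature fit can be entered by hand into the same object. Because a
single-predictor model cannot represent competing air and bone effects,
`predict` refuses (overridably) when a field has > 5% air *and* > 2%
dense bone.

The two study-table fixtures are CSV transcriptions guarded by SHA-256
checksums. Their statistics use the absolute percentage-point convention
|a−b|·100 (the relative-percent variant is also computed and emitted):
this convention reproduces the published pancreas (1.0) and prostate
(0.6) site means and the 1.4 pp largest CSF discrepancy exactly. The
published brain (1.6%) and lung (1.9%) site means differ from any
convention applied to the rounded table values (1.7 and 2.0 pp here) —
presumably computed from unrounded factors — so those two are reported
but not asserted; likewise the per-site CSF means are asserted only
below 1 pp, not 0.5 pp.

## Problem sizes and determinism

The test suite and acceptance script run the sweeps on 72³ voxel grids
at 4 mm spacing with a 4 mm beamlet lattice and 3.5 cm aperture
(hundreds of beamlets; a scatter-factor evaluation is ~0.2 s), which is
sufficient for every identity and trend property at the tolerances
stated; the library defaults (2 mm lattice, 150³ grids) refine the same
numbers by well under the lattice-refinement tolerance. All randomness
flows through explicit integer seeds; repeated runs are bit-identical.

## Known limitations

No nuclear halo, secondary particles, aperture edge scatter, Fermi-Eyges
moments, or absolute MU calibration. CSF magnitudes from the synthetic
ripple family (≤ 1.005) are smaller than the published clinical extreme
(1.044), since real compensators vary over much larger thickness ranges
and the engine lacks large-angle scatter; the direction and linearity of
the IQR relationship are reproduced, not its slope. The mid-SOBP
calculation point can sit in a gradient region for short targets; use
`point_shift_mm` to probe sensitivity.
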
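# protoscatter

Patient and compensator scatter factors for passive-scattering proton
therapy.

## The problem

Calibrating the dose per monitor unit (DMU) of a passive-scattering
proton field is usually done by measurement in a homogeneous water
phantom *without* the patient-specific range compensator. Two correction
factors connect that calibration to the treatment condition:

- **PSF** (patient scatter factor): the ratio of the dose at the
  calculation point in the patient to the dose at the same
  water-equivalent depth (WED) in a homogeneous water phantom under
  identical beam and compensator conditions,

  `PSF = d_p/c / d_vp/c`

- **CSF** (compensator scatter factor): the ratio of the water-phantom
  dose with the range compensator in place to that without it,

  `CSF = d_vp/c / d_vp/nc`

- **CPSF = PSF × CSF**, the combined correction.

Air in the beam's-eye view (lung fields) pulls the PSF below 1; dense
bone (lateral prostate fields) pushes it above 1; compensator shape
irregularity — measured as the interquartile range (IQR) of thickness
within the Highland multiple-scattering radius around the central axis —
drives the CSF above 1.

This package is for medical-physics researchers who want a fully
scripted, patient-data-free laboratory for these factors. It couples:

- a minimal analytic pencil-beam engine (Bragg-Kleeman range-energy
  relation, Bortfeld-style pristine Bragg curves, non-negative
  least-squares SOBP weights, exact voxel-boundary WED ray tracing,
  Highland scattering, Gaussian beamlet superposition),
- synthetic voxel HU phantoms with controllable composition (water box,
  lung-like air fraction, pelvis-like dense-bone fraction, slab stacks),
- range-compensator design by distal-edge ray tracing plus the IQR
  irregularity metric,
- the verification-plan workflow that defines PSF/CSF/CPSF,
- 50%-isodose / beam's-eye-view material decomposition into five HU
  classes (air, thin tissue, soft tissue, bone, dense bone),
- empirical single-predictor factor models fitted from pipeline runs, and
- the published study tables (12 Monte-Carlo-vs-pencil-beam fields, 26
  pencil-beam plans) as checksummed fixtures with their agreement
  statistics.

## Worked example

```sh
python examples/02_lung_air_sweep.py
```

```
air   0.0%  ->  PSF 1.0000   (range 17.4 cm)
air   9.7%  ->  PSF 0.9868   (range 16.7 cm)
air  19.4%  ->  PSF 0.9480   (range 14.8 cm)
air  30.6%  ->  PSF 0.9228   (range 13.4 cm)
air  40.3%  ->  PSF 0.9043   (range 12.4 cm)
air  50.0%  ->  PSF 0.8739   (range 10.8 cm)

linear fit: PSF = 1.0033 -0.00256 * air%   (r^2 = 0.989, n = 6)
```

Each row is one lung-like phantom: the generator fills the requested
fraction of the beam's-eye view with HU −800 air bands, the runner picks
a beam range covering the target, designs the compensator, and runs the
three-dose verification workflow. The PSF falls monotonically as air
replaces tissue — at ~31% air the factor is 0.92, i.e. the water-phantom
calibration would overestimate the patient dose per monitor unit by
about 8% if the PSF were ignored. The fitted line is the package's
air-percentage guideline model (`protoscatter.models`).

The other examples cover the water identity benchmark (PSF = CSF = 1 to
nine decimals), the dense-bone sweep (PSF up to 1.023 at 8.3% dense
bone), the compensator-ruggedness family (CSF rising linearly with IQR),
and the study-table report. A thin CLI mirrors the library:

```sh
protoscatter phantom --kind lung --air-fraction 0.32 --seed 7 --out lung.mha --mask-out mask.mha
protoscatter factors --phantom lung.mha --target mask.mha --beam beam.json
protoscatter report
```

## Scope

The engine is a stand-in for both a commercial pencil-beam dose
algorithm and a Monte Carlo system: it reproduces the *ratios* that
define the scatter factors and their directional dependence on
composition, not absolute dose. Monte Carlo transport, DICOM plan/CT
import, beamline modelling, and physical (TLD) measurement workflows are
out of scope. See `docs/methods.md` for the model, its assumptions, and
its limitations.
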
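# Methods

## Scope and data model

The toolkit evaluates one (possibly summed) treatment plan as a 3-D absorbed
dose field on an axis-aligned voxel grid (`DoseGrid`, Gy, cm, cc) together
with binary structure masks (`StructureMask`) on the *same* grid. Multi-grid
inputs are resampled once at ingest — trilinear for dose
(`kbpdose.io.resample_dose`), rasterisation directly onto the dose grid for
DICOM contours — and never inside the metric engine. Multi-series protocols
(46 Gy pelvic series + 30 Gy boost) are handled by voxelwise summation
(`sum_dose_grids`) because the clinic constraint template applies to the
summed dose.

## Dose-volume conventions

The discrete conventions are fixed once so that independent voxel-loop
oracles agree bit for bit:

- **VxGy** counts a voxel when its dose is **≥ x** (inclusive, the
  cumulative "receiving at least" reading). Reported in cc or % of the
  structure volume; always computed from raw voxels, never from a binned
  DVH.
- **Dq%** sorts the structure's voxel doses descending and returns the value
  at rank ⌈q/100·N⌉ — the minimum dose of the hottest q% — with no
  interpolation. This makes Dq% the generalized inverse of VxGy:
  V(≥Dq%) ≥ q% of the volume.
- **Dmax** is the maximum voxel dose (no 0.03 cc near-max variant), **Davg**
  the arithmetic voxel mean.
- Masks are strictly binary; there is no partial-voxel weighting. A
  treatment planning system typically *does* weight boundary voxels, so
  metrics on clinical exports can differ from the TPS report by a fraction
  of a voxel layer — an accepted approximation, documented rather than
  hidden, that keeps every oracle exact.
- Cumulative DVHs default to 0.05 Gy bins, finer than the 0.1 Gy / 0.1 cc
  precision at which such metrics are normally reported.

## Plan-quality indices

- Coverage rule: a plan is acceptable when D95% ≥ 95% of the prescription
  and Dmax < 107%.
- Homogeneity index HI = (D2% − D98%)/D50%; 0 for a perfectly uniform
  target dose, and invariant under uniform dose scaling.
- Paddick conformity index PCI = TV_PIV²/(TV·PIV), where PIV is the volume
  of the *whole grid* above the reference isodose. The reference isodose
  defaults to 95% of the prescription, aligning conformity with the
  coverage acceptance level; clinics that conform to the 100% isodose can
  pass `reference_isodose` explicitly. PCI is defined as 0 (with a warning)
  when no voxel reaches the reference isodose.
- The constraint template is an editable YAML list of
  (structure, metric, comparator, limit) entries; the built-in default
  carries the summed-plan limits for the peritoneal cavity (Dmax < 54 Gy,
  V45Gy < 150 cc, V15Gy < 830 cc), rectum (V40 < 40%, V60 < 50%, V70 < 25%,
  V75 < 5%), bladder (V60 < 50%, V70 < 25%), anal canal (V55 < 100%) and
  femoral heads (V52 < 10%). Template structures absent from a plan are
  reported "not evaluated" rather than failing the run.

## Prediction models

Fitting is ordinary least squares on one predictor — A = Sxy/Sxx,
B = ȳ − A·x̄, R² = 1 − SSE/SST, residual SD = √(SSE/(n−2)) — with no
intercept suppression or robust weighting: the approach is deliberately a
*simple* linear model per OAR metric, which is what makes it auditable and
cheap to refit as practice drifts. n ≥ 3 and non-degenerate predictors are
enforced.

The "95% interval" reported for a new plan is a **new-observation prediction
interval**, not a mean-response confidence band: the clinical question is
whether *this one plan* is consistent with prior practice, so the band must
cover the scatter of individual plans. Its half-width,
t·s·√(1 + 1/n + (x − x̄)²/Sxx), is minimal at the training mean and widens
for patients whose geometry sits at the edge of the training range — exactly
where the model should be trusted less.

Flag semantics: only `achieved > upper` raises a suboptimality alert;
`below_lower` is informational because lower OAR dose is clinically
desirable. No multiple-testing adjustment is applied across the seven
models: the flags are advisory prompts to re-optimise, not hypothesis tests.

Predictor units: overlap fractions in % of the OAR volume, centroid
distances as 3-D Euclidean lengths in cm, and the cavity V15Gy product
predictor as absolute overlap volume × absolute OAR volume in cc². The
product could alternatively be read as fraction × volume (cc); the registry
is config-extensible, so a clinic preferring that reading registers its own
`KbpModelSpec` — fitted models serialize to versioned JSON with all the
sufficient statistics (A, B, n, R², s, x̄, Sxx) a later prediction needs.

## Cohort statistics

Two cohorts (plans optimised with the models, WM, vs. before deployment,
WOM) are compared per metric with Mean(SD) (sample SD, n−1), the mean
difference Δ = mean(WM) − mean(WOM), and a two-sided Mann–Whitney test at
the 0.05 threshold. Exact enumeration of the U null distribution is used
when both samples have ≤ 8 observations and carry no ties; otherwise the
normal approximation with midranks, tie correction and continuity
correction. The two routes agree within 0.02 in p for sample sizes ≥ 6 on
continuous data (verified by exhaustive enumeration in the test suite); for
samples as small as 3 the normal approximation can deviate by up to ~0.04,
which is why the exact path is the default there. Δ is always computed on
unrounded means and rounded only in the formatted report — which is why a
published table rounded to one decimal can show a Δ differing in the last
digit from the difference of its printed means. Constraint-exceedance rates
return the unrounded percentage of plans violating one template entry.

## Synthetic phantom and cohorts

`make_phantom` builds a pelvic stand-in from analytic primitives on a 64³
grid at 0.2 cm isotropic spacing (12.8 cm cube): nested target ellipsoids
(PTV76 ⊂ PTV46), a posterior rectal tube, a bladder sphere, and a large
superior peritoneal-cavity box that excludes the *CTVs* (targets eroded by
the 0.5 cm PTV margin), bladder and rectum — mirroring how the cavity is
contoured clinically, and leaving a genuine cavity–PTV overlap shell. The
grid size keeps every metric well under a second while holding
discretisation error on analytic volumes below ~2%;
`sphere_offset_for_overlap` solves the sphere–sphere lens volume in closed
form so OAR positions can be chosen to hit any requested overlap fraction
(the clinically relevant range is roughly 0–30%).

`make_dose` gives each target its prescription plateau (76 Gy boost, 46 Gy
elective) with exponential falloff over a configurable length scale
(default 1.2 cm) in Euclidean distance from the target surface, plus
optional seeded Gaussian noise clipped at zero. This is a caricature of a
VMAT dose — it has no beam paths, no low-dose bath anisotropy, no
build-up — but it produces the right qualitative DVH shapes and, crucially,
is analytically checkable.

`make_cohort` synthesises training data at the *feature* level: predictor
values drawn uniformly from stated ranges and responses generated exactly as
y = A·x + B + ε with known (A, B, σ). Real training data are TPS outputs
that no phantom can recreate, so model tests check parameter recovery and
interval calibration against this known truth, while the full phantom
exercises the metric engine. The default ground-truth lines and ranges are
chosen to land on the scales a summed 76 Gy pelvic protocol shows (rectum
V60Gy rising ~0.9% per % overlap from a ~2% floor; cavity mean dose falling
~1.6 Gy/cm with distance; cavity V15Gy of hundreds of cc against cc²
products of 10⁴–10⁵). Responses are *not* clipped at zero, so the generative
model matches the fitter's assumptions exactly and recovery tests are
unbiased; physical non-negativity is a feature of real data the generator
deliberately does not enforce.

What passing these tests shows — and does not. They demonstrate that the
engine computes the stated metrics exactly, that the fitter recovers a truly
linear dose–geometry relation, and that the intervals are calibrated under
the model's own assumptions. They cannot show that any clinic's dose–geometry
relation *is* linear, that R² > 0.8 will hold on real cohorts, or that binary
masks match TPS partial-volume DVHs.

## Numerical and I/O choices

- Coordinates: physical patient coordinates in cm, voxel indices 0-based,
  grids axis-aligned, axis order (x, y, z); DICOM millimetres are converted
  at the boundary. Dose ingest honours `DoseGridScaling` and requires
  `DoseUnits == GY` and a shared frame of reference between dose and
  structure set.
- Contours are rasterised slice-wise with even-odd polygon fill
  (scikit-image), so holes and islands toggle correctly; the round trip
  through the bundled DICOM writer reproduces masks to within one voxel
  layer at boundaries.
- The portable bundle is a single versioned JSON file (float64 dose,
  bit-packed masks, both base64); wrong versions and truncated files raise
  a dedicated parse error.
- Degenerate inputs fail loudly: empty masks, mismatched grids, all-equal
  predictors, D50% = 0, invalid interval levels. The one soft case is
  PCI = 0 with a warning when the reference isodose region is empty, so a
  void plan still yields a complete evaluation.
- Simulation sizes used by the test suite and the acceptance script (50 and
  20 random phantoms for the DVH-oracle sweeps, 2000 replicates for interval
  coverage and audit-rate checks, 200 datasets for the Mann–Whitney
  agreement sweep) were chosen to give stable Monte-Carlo estimates at
  desk-scale runtimes.

## Known limitations

- Binary masks and a single shared grid approximate TPS partial-volume
  accounting (see above).
- One predictor per model by design; multivariate, exponential and
  deep-learning KBP variants are out of scope, as are dose calculation,
  optimisation, and portal-dosimetry QA.
- The phantom emulates geometry and falloff, not deliverable VMAT dose.
- Prediction intervals assume homoscedastic Gaussian residuals; heavy-tailed
  clinic residuals would make the 95% band anti-conservative.
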
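# kbpdose

A knowledge-based planning (KBP) toolkit for VMAT prostate dosimetry, written
for medical physicists and dosimetrists who want to audit treatment plans
against their clinic's own experience.

In inverse-planned radiotherapy the quality of a plan depends heavily on the
operator: without a quantitative target it is hard to know whether a rectum
V60Gy of 15% is "as good as it gets" for this patient or a suboptimal result
worth another optimisation pass. The KBP idea is to learn, from a cohort of
high-quality prior plans, how achievable organ-at-risk (OAR) dose relates to
the patient's *geometry* — quantities available before any dose is computed —
and to flag new plans that do worse than that experience predicts.

## The model

Each OAR dose metric *y* is regressed on a single geometric predictor *x*:

```
y = A·x + B + ε,   ε ~ N(0, σ²)
```

with the seven default pairings used for the summed 46 Gy pelvic series plus
30 Gy prostate boost (76 Gy total):

| response                               | predictor                                |
|----------------------------------------|------------------------------------------|
| rectum V60Gy(%), V70Gy(%)              | V_OV(Rectum/PTV76)/V_Rectum (%)          |
| bladder V60Gy(%), V70Gy(%)             | V_OV(Bladder/PTV76)/V_Bladder (%)        |
| peritoneal cavity Davg (Gy)            | ‖COM(Cavity) − COM(PTV46)‖ (cm)          |
| peritoneal cavity V45Gy (cc)           | V_OV(Cavity/PTV46)/V_Cavity (%)          |
| peritoneal cavity V15Gy (cc)           | V_OV(Cavity/PTV46) × V_Cavity (cc²)      |

For a new patient the fitted line gives the expected metric and a t-based 95%
**prediction interval** for a single new plan,

```
ŷ ± t₀.₉₇₅,ₙ₋₂ · s · √(1 + 1/n + (x − x̄)²/Sxx)
```

An achieved metric above the upper bound is flagged *suboptimal* (the cue to
re-optimise); below the lower bound is merely informational, since less OAR
dose is welcome.

Around the models the package provides the full supporting stack: a voxel
dose-volume engine (VxGy, Dq%, Davg, Dmax, cumulative DVHs, overlap volumes
and centroid distances), plan-quality indices (Paddick conformity index
TV_PIV²/(TV·PIV) and homogeneity index (D2%−D98%)/D50%), a clinic constraint
template (peritoneal cavity Dmax < 54 Gy, V45Gy < 150 cc, V15Gy < 830 cc;
rectum/bladder VxGy limits; …), Mann–Whitney before/after cohort comparison,
DICOM-RT and portable-bundle I/O, and a synthetic pelvic phantom generator so
everything is testable without patient data.

## Worked example

```python
from kbpdose import (PhantomSpec, make_phantom, make_dose, extract_features,
                     CohortSpec, make_cohort, default_model_specs, fit_model,
                     predict_with_interval, audit_plan)

# a synthetic pelvic patient: nested PTV ellipsoids, rectal tube, bladder
# sphere, peritoneal cavity; dose plateau in the targets with exponential
# falloff
spec = PhantomSpec(seed=1)
structures = make_phantom(spec)
dose = make_dose(structures, spec)

print(extract_features(structures))          # geometric predictors
# rectum_v60 11.93 %, bladder_v60 16.70 %, cavity_davg 4.28 cm,
# cavity_v45 2.03 %, cavity_v15 5653.21 cc², ...

# train on a simulated 25-plan expert cohort and fit the registry
table, _ = make_cohort(CohortSpec(n_plans=25, seed=1))
models = [fit_model(s, table[f"x_{s.model_id}"], table[f"y_{s.model_id}"])
          for s in default_model_specs()]
m = models[0]
print(m.spec.model_id, m.slope, m.intercept, m.r_squared)
# rectum_v60: A=0.931 B=1.416 R2=0.970 n=25

res = predict_with_interval(m, 11.93)
print(res.predicted, res.lower, res.upper)
# predicted 12.52 % in [9.47, 15.57]

for f in audit_plan(dose, structures, models):
    print(f.model_id, f.achieved, f.status.value)
# rectum_v60   achieved 21.01  band [ 9.47, 15.57]  above_upper
# cavity_davg  achieved  8.05  band [23.78, 32.13]  below_lower
# cavity_v15   achieved 84.08  band [17.95, 260.83] within
# ...
```

The audit reads exactly as a planner would use it: this phantom's rectum
V60Gy of 21.0% sits above the 15.6% upper bound the (simulated) clinic
experience predicts for an 11.9% overlap — a suboptimal result that warrants
another optimisation pass — while the cavity metrics are at or below
expectation.

The same pipeline is available from the shell:

```
kbpdose simulate --seed 1 --out work/
kbpdose fit --cohort work/cohort.csv --out work/models.json
kbpdose features --bundle work/phantom.json
kbpdose audit --models work/models.json --bundle work/phantom.json
kbpdose report --bundle work/phantom.json
kbpdose compare --wm wm_metrics.csv --wom wom_metrics.csv
```

`audit` also accepts `--features metrics.csv` (columns `model_id,x,achieved`)
for the manual-entry workflow, and `ingest-dicom` converts a DICOM RT Dose +
Structure Set pair into the portable bundle format.

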
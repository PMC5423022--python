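# kbpadvisor

Knowledge-based plan-quality analytics for prostate VMAT radiotherapy.

Prostate VMAT plans vary in how much they spare the rectum, and much of that
variation is driven by a single geometric feature: how much of the rectum
overlaps the planning target volume (PTV). `kbpadvisor` implements the
knowledge-based planning (KBP) approach built on that observation, for
medical-physics teams who want quantitative, cohort-derived feedback on plan
quality: it predicts the achievable mean rectum dose for a given patient's
anatomy, flags plans that fall short of historical practice, and mines
whole-cohort plan statistics.

## The model

The achievable mean rectum dose, normalised to the primary prescription dose
D<sub>Px</sub>, is modelled as a saturating exponential in the fractional
rectum–PTV overlap v = V<sub>ovr</sub>/V<sub>rec</sub>:

```
D_mean / D_Px = A + B (1 − exp(C v)),     B > 0,  C < 0
```

Two curves with shared shape (B, C) but different offsets A summarise a
historical cohort: the **OARD** ("optimal average rectum dose") curve along
the cohort's lower bound and the **MARD** ("median average rectum dose")
curve through its middle. A plan's distance to a prediction is the relative
model excess

```
δ = (D_mean − D_pred) / D_pred
```

which is dimensionless, so plans can be compared across prescriptions. A
plan is **OPTIMAL** when its mean rectum dose is at or below the OARD
prediction, **NOT_ACCEPTABLE** when above the MARD prediction, and
**ACCEPTABLE** in between.

The package contains:

* `dose_geometry` — voxel engine: contour rasterization, ROI volumes,
  overlap fractions, cumulative DVHs, Dx/Vx, mean dose, conformity index;
* `sparing_model` — the curve model, reproducible quantile (pinball-loss)
  fitting of the OARD/MARD pair, δ, and the three-way verdict;
* `cohort_miner` — per-plan metric extraction, cohort tables, validation
  patient selection by δ, Welch and paired t-test comparisons;
* `advisor` / `cli` — the clinical advisory workflow plus a `kbpadvisor`
  command-line tool (`mine`, `fit`, `advise`, `compare`, `simulate`);
* `synthetic_fixtures` — phantom anatomies built with the trial-protocol
  margin recipe (PTV3 = prostate + 5 mm, 0 mm posteriorly; PTV2/PTV1 from
  prostate ± seminal vesicles + 10 mm), a dose emulator with controllable
  ground-truth δ, and cohort scatter generators;
* `io` — DICOM RT-STRUCT/RT-DOSE/RT-PLAN readers and writers plus a
  plain-text plan format used by the test-suite.

## Worked example

Fit a curve pair to a simulated 97-patient cohort, build a phantom whose
true δ is +0.12, and ask for advice:

```
$ kbpadvisor simulate --what points --seed 11 --n 97 --out points.csv
$ kbpadvisor fit points.csv --out model.json
fitted pair: OARD A=0.288, MARD A=0.328, B=0.548, C=-2.045 -> model.json

$ kbpadvisor simulate --what phantom --seed 5 --overlap 0.25 --delta 0.12 --out plan05
$ kbpadvisor advise plan05 --model model.json
knowledge-based plan check
  prescription:        74.0 Gy in 37 fractions
  rectum-PTV1 overlap: 0.244
  mean rectum dose:    45.12 Gy
  OARD prediction:     37.23 Gy
  MARD prediction:     40.14 Gy
  relative excess:     +0.212
  verdict:             NOT_ACCEPTABLE
  guardrails:
    total_mu_le: target 600, achieved 430 [pass]
```

The phantom's anatomy put 24.4 % of the rectum inside PTV1; for that overlap
the fitted lower-bound curve predicts a 37.23 Gy mean rectum dose as
achievable. The plan's actual 45.12 Gy is 21 % above that prediction and
above the cohort median curve, so the advisor reports the plan as not
acceptable — a planner should keep optimising. The exit status (0 optimal,
1 acceptable, 2 not acceptable) makes the verdict scriptable.

The same checks are available as library calls (`predict`, `fit_pair`,
`classify`, `extract_record`, `advise`); see `docs/methods.md` for the
modelling details and defaults.

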
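# cvmstage

Quantitative staging of skeletal maturity from the cervical vertebrae on
lateral cephalograms, for orthodontic treatment timing in female
adolescents.

Craniofacial orthopedics needs to know where a growing patient stands
relative to the pubertal growth spurt. The cervical vertebrae maturation
(CVM) method reads this from the shapes of the C2–C4 vertebral bodies,
which are visible on the lateral cephalogram that orthodontists take
anyway: lower borders flatten → develop concavities, bodies grow from
trapezoid to rectangular to square, and the spaces between bodies close.
Visual staging of these changes is notoriously examiner-dependent.
`cvmstage` implements an objective alternative: a published regression
staging system over four condensed stages iCS1–iCS4 (prepuberty, pubertal
peak, pubertal slowdown, post-puberty), driven entirely by landmark
coordinates.

The package provides, end to end:

- **`landmarks`** — I/O and validation for 15-landmark coordinate tables
  (C2 {a, p, d}; C3/C4 {la, lp, ua, up, um, d}) and feature tables, with an
  axis-convention flag for y-down digitizer exports;
- **`morphometry`** — the 24 morphometric parameters: concavity depths
  (D2–D4), anterior/posterior body heights (AH, PH), upper/lower widths
  (UW, LW), six ratios, antero-superior angles (@2–@4), and four
  inter-vertebral distances;
- **`model`** — the published cascade staging model (see below), shipped as
  versioned constants `primary-2024` / `correction-2024`;
- **`fitting`** — the model-development pipeline: Spearman screening,
  proportional-odds and binary-logistic maximum likelihood, backward
  elimination, Brant (parallel-lines) test, and VIF diagnostics;
- **`evaluation`** — confusion matrices and per-stage precision / recall /
  F1 with multiclass accuracy;
- **`synthetic`** — seeded generators for landmark-level cohorts calibrated
  to the published cohort statistics, and feature-level cohorts drawn from
  a known ordinal model for recovery experiments;
- **`cvmstage`** — a CLI chaining simulate → extract → predict → fit →
  evaluate → report.

## The staging model

The primary model is a proportional-odds (cumulative-logit) regression
over the four stages:

    P(y ≤ j | x) = σ(α_j − βx),    j = 1, 2, 3
    P(y = j | x) = P(y ≤ j) − P(y ≤ j−1)

with linear predictor (raw feature scale: years, mm, degrees, ratio)

    βx = 3.172·age + 28.642·(D3:AH3) + 0.727·@4 + 0.453·(C3lp–C4up)

and thresholds α = (32.921, 45.460, 62.065). The predicted stage is the
probability argmax, ties resolved toward the more mature stage.

Because the pubertal-slowdown stage iCS3 is the hardest to separate from
the adjacent post-pubertal stage, a binary logistic correction is applied
whenever the primary prediction lands in {3, 4}:

    P(iCS = 3 | x) = σ(51.828 − (2.139·age + 0.313·@4 + 1.444·PH4))

decided at probability 0.5. Primary predictions of stage 1 or 2 are never
altered.

## Worked example

```python
from cvmstage import predict_cascade

fv = {"age": 12.3, "D3_AH3": 0.146, "ang4": 10.4, "C3lp_C4up": 3.40, "PH4": 11.1}
pred = predict_cascade(fv)
print("linear predictor  :", round(pred.linear_predictor_primary, 3))
print("stage probabilities:", [round(p, 4) for p in pred.probabilities])
print("P(iCS3) correction:", round(pred.p_ics3, 4))
print("final stage       :", pred.stage_final)
```

prints

```
linear predictor  : 52.298
stage probabilities: [0.0, 0.0011, 0.9989, 0.0001]
P(iCS3) correction: 0.998
final stage       : 3
```

A 12.3-year-old with a moderate C3 concavity ratio (D3:AH3 = 0.146) has a
linear predictor of 52.3, between α₂ = 45.5 and α₃ = 62.1, so virtually
all probability mass falls on stage 3; the correction model agrees
(P(iCS3) ≈ 0.998) and the final call is iCS3 — pubertal slowdown.

The same pipeline on a full synthetic cohort, from the shell:

```bash
cvmstage simulate --n-per-stage 120 --seed 7 --out-dir run
cvmstage extract  --landmarks run/landmarks.csv --out run/features.csv
cvmstage predict  --features run/features.csv --cascade --out run/predictions.csv
cvmstage evaluate --predictions run/predictions.csv --truth run/features.csv \
                  --out-dir run/eval
```

ends with

```
accuracy 0.8833 (88.33%) on n=480
```

i.e. the packaged model recovers the generator's stage labels for 88% of
480 synthetic subjects (the published accuracy on the real development
cohort, 93.96%, is a property of the original radiographs and is not
claimed reproducible from synthetic data; see `docs/methods.md`).

## Layout

```
src/cvmstage/       library (landmarks, morphometry, model, fitting,
                    evaluation, synthetic, published, cli)
tests/              pytest suite, incl. end-to-end scientific checks
scripts/acceptance.py   reproduction script
docs/methods.md     models, assumptions, calibration, numerics, limitations
```
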
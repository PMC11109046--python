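# Methods

This note records the models, conventions, calibration choices and known
limitations of `cvmstage`, at the level of detail a maintainer or a
careful user needs. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## Coordinate and landmark conventions

Internal coordinates are millimetres with y increasing upward
(anatomically superior). Digitizers that export image coordinates (y
down) are handled by the `convention="image"` flag on the readers, which
negates y. Every morphometric parameter is built from unsigned
point-to-line distances, unsigned vertex angles and point-to-point
distances, so all 24 features are invariant under rigid motion *and*
reflection; the convention flag therefore cannot change any extracted
value (tested to 1e-9).

The 15-landmark schema is C2 {a, p, d} and C3/C4 {la, lp, ua, up, um, d}:
a/la and p/lp are the anterior and posterior ends of the lower border,
ua/up the superior ends of the anterior/posterior borders, d the most
superior point of the lower border (its apex when the border is concave),
um the midpoint of the upper border. Validation enforces exactly these 15
labels per subject, finite coordinates, ua/up superior to la/lp, and a
configurable age plausibility window (default 4–25 years; the reference
cohort spans 6–19).

## Morphometry

- **Concavity depths D2, D3, D4** are the perpendicular distance of each
  vertebra's lower-border apex `d` to the infinite line through that
  border's endpoints (C2: a–p; C3/C4: la–lp). A flat border gives D ≈ 0.
  The three depths are defined identically across vertebrae; this is the
  only reading consistent with the reference cohort's descriptive
  statistics (pooled D3 ≈ 1.07 mm, D3:AH3 ≈ 0.11, i.e. depths, not body
  heights) and with the magnitude of the D3:AH3 slope in the staging
  model. `um` is retained as a required landmark for schema fidelity but
  feeds no measurement; a *signed* depth variant (positive = apex superior
  to the border line) is exposed as `signed_concavity_depths` for
  diagnostics only and never enters any model.
- **Heights and widths.** AH/PH are the distances of ua/up to the
  lower-border line; UW/LW are the distances of ua/la to the
  posterior-border line (up–lp). All are unsigned point-to-infinite-line
  distances, implemented as |cross(b−a, p−a)|/|b−a| and cross-checked in
  tests against a brute-force 1-D projection search (agreement < 1e-6 mm
  on 1000 random triples).
- **Angles @2–@4** are the unsigned angle at the posterior-inferior
  landmark (C2p, C3lp, C4lp) between the rays to `d` and to the
  anterior-inferior landmark. Numerically the angle is computed as
  atan2(|u×v|, u·v), not arccos of the normalized dot product: the two are
  mathematically identical, but arccos loses roughly half the significand
  for the near-collinear rays that flat (stage-1) borders produce, and
  would break rigid-motion invariance at the 1e-9 level. A perfectly flat
  border yields an angle of 0°, the degenerate limit of the concavity
  angle.
- **Ratios** (D:AH, PH:UW, PH:LW per vertebra) are stored explicitly and
  validated against their numerator/denominator fields to 1e-9 relative;
  a zero denominator is an error naming the subject.
- Coincident landmarks that would degenerate a measuring line raise a
  `GeometryError` naming the two landmarks.

## The cascade staging model

Link convention: P(y ≤ j | x) = σ(α_j − βx) with strictly increasing
thresholds, so larger βx means a more mature stage; all packaged slopes
are positive, matching the uniformly positive stage correlations of the
informative features. Per-stage probabilities are differences of
consecutive cumulative probabilities, evaluated with `scipy.special.expit`
(finite for any |βx|; the sum-to-one identity holds to < 1e-9 over 10 000
random inputs by construction). The predicted stage is the argmax with
ties resolved toward the more mature stage, mirroring the clinical rule
that in-between morphology is assigned to the later stage.

The packaged coefficients apply to **raw** feature values (years, mm,
degrees, ratio), not z-scores. The thresholds (32.9–62.1) are commensurate
with βx evaluated at the cohort's pooled feature means (46.895, computed
independently by scalar arithmetic in the tests); on z-scored inputs βx
would be near 0 and every subject would be called stage 1. Z-scoring in
the original development is therefore read as part of feature screening
(where it is a no-op for rank-based Spearman screening anyway), not of the
final model. This is an interpretation and is flagged as such.

The correction model is triggered when the primary stage is 3 or 4 — the
two classes it was trained to separate — with decision cut 0.5 on
P(iCS = 3) = σ(α − β_c x). Both the trigger set and the cut are
configurable; stage-1/2 primary calls are never modified (enforced by an
invariant test). The exact combination rule used in the original study is
not spelled out; the {3, 4}-trigger is this package's operationalization.

Models serialize to JSON (binary64 floats round-trip exactly); packaged
constants are addressable by name (`primary-2024`, `correction-2024`).

## Model development pipeline

Fitting is delegated to statsmodels: `OrderedModel(distr="logit")` for the
proportional-odds MLE — its parameterization (α_j − xβ, thresholds encoded
as α₁ plus exp-increments, guaranteeing order) is exactly the one the
module exposes — and `Logit` for the binary model, refit on the
complement class so slopes carry the maturation sign and α = −intercept.
Threshold standard errors are delta-method transforms of the exp-increment
encoding. Reported inference is Wald ((B/SE)², χ²₁ p-values, CI = B ±
1.96·SE), matching the layout of the original coefficient tables.
Convergence uses BFGS with gradient tolerance 1e-6, max 200 iterations
(non-convergence warns and is flagged, never silent). A standardized
slope exceeding 50 triggers a quasi-separation warning. Singular-Hessian
corner cases (tiny n, collinear designs) fall back to a pseudo-inverse of
the analytic Hessian with undefined SEs reported as NaN.

The pipeline (`develop_model`) is: univariate Spearman screen at p < 0.05
(no multiplicity correction, deliberately, as in the original
development), multivariable proportional-odds fit on the candidates, then
backward elimination of the largest non-significant Wald p (≥ 0.05) with
refitting until all retained terms are significant; undefined p-values
count as non-significant. Diagnostics on the final model:

- **Brant test** (implemented here; no Python implementation exists): the
  J−1 cumulative binary logits P(y > j) are fitted separately and a Wald
  χ² compares their slope vectors, using the joint covariance implied by
  the overlapping binary responses (off-diagonal blocks built from
  weights π_l − π_j·π_l for j ≤ l); omnibus df = (J−2)·k plus
  per-variable tests with df = J−2. With a single cutpoint (J = 2) the
  test is undefined and raises. Monte-Carlo calibration under exact
  proportional odds (500 replicates, n = 400, k = 2) keeps the type-I
  error inside [0.03, 0.07]; power against strongly cutpoint-varying
  slopes is ≈ 1 at n = 1000.
- **VIF** 1/(1−R²) with tolerance = 1/VIF, flagged at VIF ≥ 5 i.e.
  tolerance < 0.2 (a tolerance *greater than 2* is impossible, since
  tolerance ≤ 1 by definition). Perfect collinearity reports VIF = ∞,
  flagged, rather than failing.

## Evaluation conventions

Confusion matrices are 4×4, rows = expert stage, columns = predicted.
Per-stage metrics are one-vs-rest; overall accuracy is the multiclass
trace/N (the per-class TN terms cancel in the 4-class view — trace/N is
also the only reading under which the reference accuracies 93.96% and
92.50% follow from the printed per-stage recalls and cohort sizes, which
the test suite reconstructs). 0/0 metrics are reported as NaN
("undefined"), never coerced to 0 or 1; macro averages skip undefined
entries. The whole metric stack is cross-checked against scikit-learn on
random label sets; it is implemented directly because sklearn's
`zero_division` coercion cannot express the undefined convention.

One printed reference cell is internally inconsistent (modified model,
validation cohort, iCS3: printed F1 0.9456 vs harmonic mean 0.9231 of its
printed precision/recall pair); the package computes 0.9231 and the
discrepancy is documented in `cvmstage.published`. A second cell
(modified/primary/iCS3) differs only because the original F1 was computed
from unrounded counts (230/237 = 0.97046); the rounded pair gives 0.97044,
within 1e-4.

## Synthetic cohorts

`simulate_landmarks` emulates a balanced female-adolescent cohort. Each
stage has a geometric template: body heights/widths for C3/C4, C2 lower
border width, concavity depths, anterior inter-body gaps, and a
truncated-normal age distribution whose mean/SD/range follow the reference
cohort's per-stage demographics (7.6 ± 0.8 [6.0–12.2] → 15.7 ± 1.3
[11.8–19.0] years). Landmarks are placed analytically — quadrilateral
corners from heights/widths with a horizontal lower border and vertical
posterior border, `d` at the lower-border midpoint raised by the depth,
`um` at the upper mid-border — then Gaussian parameter noise and a random
rigid motion (±10°, ±20 mm) are applied per subject. With all noise SDs
zero the extractor inverts the constructor exactly (tested to 1e-9,
including the derived posterior-gap distances and angles
atan(2·depth/width)).

Calibration: the reference study prints only pooled means/SDs and stage
correlations, not per-stage feature means, so the split of pooled variance
into a between-stage trend and within-stage noise is a free choice. The
default templates interpolate linearly across stages around the pooled
means with trend magnitudes chosen so that pooled means/SDs land near the
printed values (e.g. pooled D3 ≈ 1.06 vs 1.07 ± 0.80 printed; D3:AH3 ≈
0.11; @4 ≈ 7.8° vs 7.74°) and all stage-correlation signs match (positive
throughout except the four inter-vertebral distances). Within-stage noise
SDs are 1.0 mm (heights), 1.25 mm (widths), 0.35 mm (depths, clamped at 0
— a flat border is a genuine anatomical floor, so the clamp's point mass
at 0 is a feature), 0.6 mm (gaps). The template set is versioned
(`default-1`) and validated for monotone morphology (depths non-decreasing,
gaps non-increasing across stages).

What the generator does **not** emulate: real vertebral shape
irregularity (borders are exact polygon edges), landmark digitization
error structure, within-subject correlation between adjacent vertebrae
beyond the shared stage, observer disagreement in the ground-truth
stages, and the true conditional feature distributions given stage.
Consequently, the ≈ 88% agreement of the packaged cascade with the
generator's labels on the default cohort is a smoke-level consistency
check, not a reproduction of the published 93.96%/92.50% accuracies,
which are properties of the original radiographs.

`simulate_features_from_model` draws Gaussian features (optionally
equicorrelated or with a full correlation matrix, plus independent
standard-normal nuisance columns) and samples stages from a known
proportional-odds model — the harness for the recovery and
selection-consistency experiments. Randomness in both generators is
counter-based per subject (`SeedSequence(seed, spawn_key=...)`), so
cohorts are reproducible and stable under reordering.

### Selection-consistency experiment design

With the four informative features drawn *independently* at their pooled
marginal scales, the weakest term (C3lp–C4up: partial effect 0.49 against
a linear-predictor SD ≈ 11) has only ≈ 50% power in the marginal Spearman
screen at n = 2000, so a marginal screen can never reliably recover it.
That is not how morphometric data behave: measurements of the same spine
are mutually correlated, and it is exactly that correlation that gives a
weak partial predictor a detectable marginal association. The experiment
therefore uses an equicorrelated (ρ = 0.4) Gaussian design for the four
informative features plus four independent nuisance features. Under that
design the pipeline retains exactly the informative set in ≥ 90 of 100
seeded runs.

## Problem sizes and runtimes

The default test suite uses cohorts of 8–200 subjects per stage for
deterministic checks, and the following sizes for the stochastic
calibration suite: parameter recovery 100 replicates × n = 5000; Brant
null calibration 500 replicates × n = 400; selection consistency 100 runs
× n = 2000. These sizes were chosen to keep each Monte-Carlo standard
error well below the width of its acceptance band while the full suite
runs in about a minute on one core. `scripts/acceptance.py` uses
n = 120/stage for the synthetic end-to-end run and a single n = 5000
recovery fit, finishing in a few seconds.

## Known limitations

- The staging model is specific to the reference population (Chinese
  female adolescents); no male or other-ancestry coefficients are shipped.
- Whether the original coefficients were reported on the raw or
  standardized scale is an interpretation (raw, for the reasons above).
- The generator's per-stage feature means are package choices constrained
  only by pooled statistics; per-stage conditional behavior (e.g. exact
  stage-wise SDs) is not calibrated.
- Calibration of digitized pixels to millimetres is assumed done upstream
  of the landmark tables.
- No ROC/AUC or probability-calibration analysis; the evaluation follows
  the confusion-matrix framework of the reference study.
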
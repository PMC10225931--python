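# Methods

This note records the modelling and numerical choices behind `migsfis`,
what the synthetic data generator does and does not emulate, and the
known limitations.

## Data model and preprocessing

A cohort is a table of six predictors — age (years), visual acuity
(LogMAR), intraocular pressure (mmHg), visual-field mean deviation (dB),
daily drop count, glaucoma-type code 1..6 — and an optional treatment
code 1..4. Cleaning drops (never imputes) any row with a non-finite
field or an out-of-range code, because a treatment advisor should not
fabricate clinical values.

Inputs are normalized by dividing each feature by its largest absolute
value on the training cohort, which maps the training data into [−1, 1]
per feature without standardizing variances; test data may exceed the
interval and is deliberately not clipped. The treatment code is *not*
normalized: the model regresses directly onto the integer class scale
because the final decision is a rounding of the crisp output.

Splitting is a seeded random permutation: `round(0.60·N)` rows form the
training share, of which `floor(0.05·…)` are held out as a validation
slice for training checkpoints, and the remaining 40% are never seen
until evaluation. For an audit-sized cohort of 372 this gives
212 / 11 / 149 rows.

## Rule extraction

Subtractive clustering runs on the joint 7-D (inputs, class code)
vectors affinely scaled to the unit box, so that each cluster couples a
feature pattern with its outcome and the rule count adapts to the data.
Potentials use α = 4/r² and the subtraction kernel β = 4/(1.25·r)², with
accept/reject thresholds 0.5 and 0.15 of the first potential — the
classical formulation; all four knobs are exposed but only the radius r
(default 0.15) is normally touched. Ties in the potential argmax break
to the lowest row index, which makes the center sequence deterministic.
Borderline candidates are kept when `d_min/r + P/P₁ ≥ 1`, otherwise
their potential is zeroed and selection continues.

At r = 0.15 on a few hundred rows of quantized clinical data most
distinct feature patterns become their own cluster (roughly one to two
rows per rule). This granular regime is intentional: it is what the
stated radius produces at this cohort scale, and the per-class
structure is then carried by the premise geometry rather than by a
small curated rule base.

Each cluster becomes one rule. Premise centers are the cluster center's
input coordinates mapped back from the unit box; premise widths follow
the classical radius conversion σ_d = r·(max_d − min_d)/√8 on the
training range of each input, floored at 1e-6 for degenerate
dimensions. Consequents are linear (first-order Sugeno) by default —
constant consequents are available via a flag — and are initialized by
the global least-squares solve below.

## Hybrid training

Each epoch alternates:

1. **Consequent solve.** With premises frozen the model output is linear
   in all R·7 consequent coefficients, with regressors
   (w_c/Σw)·(x, 1). One minimum-norm `lstsq` solve fits them all; the
   training SSE never increases. When R·7 exceeds the row count the
   solve interpolates and the minimum-norm property is what pins the
   solution down.
2. **Premise step.** Batch gradient descent on SSE over all centers and
   widths, computed analytically from the product/weighted-average
   forms. The step size is the Euclidean length of the update (the
   gradient supplies only the direction), grown ×1.1 after four
   consecutive training-error decreases and shrunk ×0.9 after two
   consecutive up-down oscillations, counters resetting after each
   adjustment. Widths are clamped at 1e-6. Samples whose total firing
   underflows contribute zero gradient rather than 0/0.

Defaults: 50 epochs, initial step 0.01. Convergence is epoch-capped;
the returned model is the checkpoint with the lowest validation RMSE
(first occurrence on ties), which is the only over-fitting control — at
granular radii the training error is near zero from epoch 0 and the
premise gradient vanishes, so the checkpoint simply returns the
initialized system.

## Decision and evaluation

The crisp output rounds half-up to the nearest class and clamps into
1..4, so the band [k−0.5, k+0.5) maps to k. Per-class one-vs-rest
counts come from the 4×4 confusion matrix (TP the diagonal cell, FP the
rest of its column, FN the rest of its row, TN the remainder), from
which the eight ratios TPR, TNR, PPV, NPV, FPR, FNR, FDR, ACC are
computed exactly; zero denominators yield NaN rather than an error, and
aggregate summaries average over classes skipping NaNs. The Pearson
test compares actual and estimated codes with the exact t-distribution
p-value (n−2 degrees of freedom). Decision surfaces evaluate the model
on a grid over each of the C(6,2) = 15 input pairs, pinning the other
four inputs at the training means (configurable), each axis spanning
the observed min..max.

## Synthetic cohort generator

Real MIGS audit data is request-only, so the test bed is synthetic. The
generator emulates four properties of a single-center audit table:

- **Marginals.** Truncated normals per feature — age (77.36, 3.819) on
  [40, 97], VA (0.3, 0.25) on [0, 1.4], IOP (18.54, 4.62) on [6, 40],
  VF (−7.65, 7.2) on [−33, 1.11], drops (2.12, 1.08) on [0, 5] —
  treating each published ± figure as an SD and the published absolute
  maximum as the upper bound, with clinically sensible lower bounds.
- **Quantization.** Values snap to measurement precision: whole years
  and mmHg, 0.1-LogMAR and 0.1-dB steps, integer drop counts. This
  also reproduces the duplicate-pattern density of real tables, which
  is why a real audit yields fewer clusters than rows.
- **Severity correlation.** A Gaussian copula couples the markers of
  disease burden — IOP–drops 0.85, IOP–VF −0.70, VF–drops −0.75,
  VF–VA −0.50, plus weak age links — reflecting that pressure,
  medication load and field loss rise and fall together. Identity (an
  independent draw) and any other positive-definite matrix are
  accepted. Glaucoma type is uniform over the six codes by default; a
  skewed preset matching the audit's mean of 5.13 is provided.
- **Planted rules.** Labels follow an ordered first-match rulebook with
  a default class; label noise replaces a configurable fraction with
  uniform random classes. The default book keys the treatment on the
  glaucoma-type group (codes 1–2 → class 1, codes 5–6 → class 4) and
  splits the middle types by medication burden (≥3 drops → class 2,
  else class 3).

The default rulebook's design is deliberate. Class boundaries sit on
the coarse discrete features (type code, drop count), whose unit steps
carry real distance in the normalized space, so a local model can
recover them; the correlated severity block makes each class region
coherent across several features at once; and class codes are assigned
so regions adjacent in feature space mostly carry adjacent codes, which
means the weighted-average defuzzification rounds to the nearer class
instead of an in-between one. Boundaries on near-continuous features
(e.g. a raw IOP cut on otherwise independent features) are not
recoverable by any local method at this cohort size; the generator
avoids making them the default, but arbitrary rulebooks — including
threshold books on continuous features — are supported for stress
tests.

What the generator does **not** emulate: longitudinal follow-up visits,
complications and re-interventions, site effects, measurement error
beyond quantization, and any real dependence of surgeon choice on
factors outside the six predictors. Passing the synthetic benchmark
therefore shows the pipeline can recover a planted decision structure
of realistic shape at audit scale — not that it reproduces real
clinical performance.

Under the frozen defaults the full pipeline (n = 400, noiseless labels,
60/40 split, radius 0.15, 10 epochs) reaches a mean held-out accuracy
of 0.92 across seeds 0–19 and beats the regression comparator on mean
per-class accuracy on every one of those seeds; accuracy decays toward
chance as label noise grows. These numbers are recomputed, not quoted:
the acceptance script and test suite rerun them.

## Numerical choices and degenerate inputs

- Product t-norm (differentiable) and weighted-average defuzzification;
  Mamdani centroid-of-area is out of scope.
- Minimum-norm `lstsq`/`pinv` solutions everywhere a system can be
  rank-deficient; residual orthogonality is tested to 1e-8.
- Normalization round-trip tolerance 1e-12 relative; model JSON stores
  full double precision and round-trips bit-identically.
- Constant dimensions: unit-box scaling maps them to 0.5; premise
  widths floor at 1e-6; an all-zero feature column is a hard error at
  normalizer fit.
- The regression baseline has no intercept by default (matching its
  printed form); a flag adds one.
- Problem sizes in the test suite (cohorts of 150–400, fixtures of
  ≤ 25 points for the clustering oracle, 200-sample self-recovery runs)
  keep the whole suite and the acceptance script in the seconds-to-
  minutes range while still exercising the granular-rule regime.

## Known limitations

- With radius 0.15 at audit scale the trained system is effectively a
  smooth nearest-pattern interpolant; its accuracy ceiling is that of a
  local method, and premise fine-tuning contributes nothing once the
  consequent solve interpolates (zero training gradient).
- Regressing onto ordinal class codes makes boundary mixing sensitive
  to how codes are assigned to clinically adjacent groups; with an
  adversarial code permutation the same geometry scores worse.
- The evaluation rubric treats classes symmetrically; no
  cost-sensitive weighting of clinically worse mistakes.
- ROC/AUC are not provided: a single crisp output per patient admits no
  natural per-class score ordering in this architecture.
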
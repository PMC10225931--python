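# migsfis

Fuzzy-inference treatment advice for minimally invasive glaucoma surgery
(MIGS).

Glaucoma surgeons choosing between modern MIGS procedures — iStent
inject, iStent combined with endoscopic cyclophotocoagulation (ICE2),
the PreserFlo MicroShunt, and the XEN-45 gel stent — weigh several
baseline measurements at once: age, best-corrected visual acuity
(LogMAR), intraocular pressure (mmHg), Humphrey visual-field mean
deviation (dB), the number of daily IOP-lowering drops, and the type of
glaucoma. `migsfis` implements an adaptive neuro-fuzzy inference system
(ANFIS) that learns this mapping from a labeled cohort and then advises
one of the four treatment categories for a new patient, together with
the multiclass evaluation rubric used to judge it, a linear-regression
comparator, and a synthetic-cohort generator so the whole pipeline can
be exercised without access to protected clinical data.

## The model

The classifier is a first-order Takagi–Sugeno fuzzy system. Rule *c* has
Gaussian premises and a linear consequent over the six normalized inputs
x = (x₁, …, x₆):

    IF x₁ is A_c1 AND … AND x₆ is A_c6  THEN  f_c(x) = p_c · x + r_c

with membership μ(x_d) = exp(−(x_d − m_cd)² / 2σ_cd²), product t-norm
firing strength w_c(x) = Π_d μ(x_d), and the crisp output

    y(x) = Σ_c w_c f_c(x) / Σ_c w_c ,

the firing-strength-weighted centroid of the rule outputs. Rounding y to
the nearest integer in 1..4 (so 1.5–2.4 → 2) yields the advised class.

Rules are seeded by subtractive clustering of the joint input+output
vectors scaled to the unit box: each data point's potential
P_i = Σ_j exp(−4‖x_i − x_j‖²/r²) measures local density; the
highest-potential point becomes a cluster (hence rule) center, its
neighborhood is subtracted away, and the loop repeats. One radius of
influence r (default 0.15) controls the granularity. Training is the
classical hybrid: an exact global least-squares solve of all consequent
coefficients alternating with batch gradient descent on the premise
centers and widths, checkpointed on a small validation slice.

The regression comparator fits TC = a₁·Age + a₂·VA + a₃·VF + a₄·IOP +
a₅·Drops + a₆·Type by pseudoinverse on the raw features and thresholds
with the same rounding rule.

Per class the rubric reports TPR, TNR, PPV, NPV, FPR, FNR, FDR and ACC
from one-vs-rest counts extracted from the 4×4 confusion matrix, plus a
Pearson correlation test between actual and estimated codes. Ratios with
a zero denominator are reported as NaN.

## Worked example

Generate a synthetic audit-sized cohort, train, and score the held-out
40%:

```
$ migsfis synth --n 372 --seed 7 --out-dir cohort
INFO migsfis: wrote 372-row cohort to cohort/cohort.csv

$ migsfis train --input cohort/cohort.csv --radius 0.15 --epochs 10 --seed 7 --out-dir run
INFO migsfis: trained 212 rules; best epoch 0; 149 test rows held out

$ migsfis evaluate --model run/model.json --input run/test.csv --out-dir eval
INFO migsfis: accuracy 0.9262 over 149 samples
```

The 372 rows split 60/40 into 223 training (11 of them validation) and
149 test patients; clustering at radius 0.15 yields one fuzzy rule per
distinct training pattern (212 here). `eval/metrics.csv` holds the
per-class rubric — for example class 1 reaches TPR 0.978 and per-class
ACC 0.987 on this run — and `eval/summary.yaml` the overall numbers:

```
accuracy: 0.9261744966442953
mean_class_acc: 0.9630872483221475
pearson_r: 0.9632334976979943
pearson_p: 8.46776387268482e-86
```

`migsfis surfaces` exports the C(6,2) = 15 pairwise decision-surface
grids, and `migsfis compare` produces the side-by-side ANFIS vs
regression rubric tables.

Everything is also available as a library:

```python
from migsfis import SyntheticConfig, generate_cohort
from migsfis.pipeline import train_pipeline, evaluate

cohort = generate_cohort(SyntheticConfig(n=372, seed=7))
model, history, test = train_pipeline(cohort, radius=0.15, epochs=10, seed=7)
print(evaluate(model, test).accuracy)
```

## Layout

- `src/migsfis/cohort.py` — tabular data model, CSV I/O, cleaning,
  absolute-maximum normalization, 60/40/5% splitting
- `src/migsfis/subclust.py` — subtractive clustering
- `src/migsfis/fuzzy.py` — Takagi–Sugeno system, rule construction, JSON
  model files
- `src/migsfis/anfis.py` — hybrid least-squares/gradient training
- `src/migsfis/classify.py` — thresholding, confusion matrix, rubric,
  Pearson test, decision surfaces
- `src/migsfis/regression.py` — pseudoinverse regression baseline
- `src/migsfis/synth.py` — synthetic cohort generator
- `src/migsfis/cli.py` — `migsfis` command-line interface

See `docs/methods.md` for the modelling decisions and their rationale.
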
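"""Treatment-class decisions and the multiclass evaluation rubric.

The fuzzy system emits a continuous value on the 1..4 treatment-code
scale; rounding to the nearest integer (clamped into the code range)
yields the advised MIGS category. Evaluation extracts one-vs-rest
TP/TN/FP/FN counts per class from the multiclass confusion matrix and
reports eight per-class ratios, plus a Pearson correlation test between
actual and estimated codes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fuzzy import FISModel, evaluate_fis

METRIC_NAMES = ("tpr", "tnr", "ppv", "npv", "fpr", "fnr", "fdr", "acc")


def round_to_class(y, n_classes: int = 4):
    """Nearest-integer class code, half-up, clamped into 1..n_classes.

    The band [k - 0.5, k + 0.5) maps to k, so 1.5 -> 2 and 2.4 -> 2;
    out-of-range outputs clamp to the nearest valid code.
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    arr = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite output cannot be classified")
    cls = np.clip(np.floor(arr + 0.5), 1, n_classes).astype(int)
    return int(cls) if np.isscalar(y) or arr.ndim == 0 else cls


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ClassCounts:
    """One-vs-rest TP/TN/FP/FN for a single class; sums to the total."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    tpr: float
    tnr: float
    ppv: float
    npv: float
    fpr: float
    fnr: float
    fdr: float
    acc: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.tpr, self.tnr, self.ppv, self.npv,
                self.fpr, self.fnr, self.fdr, self.acc)


def confusion(true_codes, pred_codes, n_classes: int = 4) -> ConfusionMatrix:
    t = np.asarray(true_codes, dtype=int)
    p = np.asarray(pred_codes, dtype=int)
    if t.shape != p.shape:
        raise ValueError("true and predicted code vectors differ in length")
    for name, v in (("true", t), ("predicted", p)):
        if v.size and (v.min() < 1 or v.max() > n_classes):
            raise ValueError(f"{name} codes outside 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (t - 1, p - 1), 1)
    return ConfusionMatrix(counts=counts)


def class_counts(m: ConfusionMatrix, k: int) -> ClassCounts:
    """One-vs-rest extraction for class k (1-based).

    TP is the diagonal cell; FP the rest of column k; FN the rest of
    row k; TN everything else.
    """
    if not 1 <= k <= m.n_classes:
        raise ValueError(f"class {k} outside 1..{m.n_classes}")
    i = k - 1
    tp = int(m.counts[i, i])
    fp = int(m.counts[:, i].sum() - tp)
    fn = int(m.counts[i, :].sum() - tp)
    tn = m.total - tp - fp - fn
    return ClassCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den else float("nan")


def metrics(c: ClassCounts) -> ClassMetrics:
    """The eight per-class ratios; zero denominators yield NaN."""
    return ClassMetrics(
        tpr=_ratio(c.tp, c.tp + c.fn),
        tnr=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
        fpr=_ratio(c.fp, c.fp + c.tn),
        fnr=_ratio(c.fn, c.tp + c.fn),
        fdr=_ratio(c.fp, c.tp + c.fp),
        acc=_ratio(c.tp + c.tn, c.total),
    )


def metrics_table(m: ConfusionMatrix) -> pd.DataFrame:
    """Per-class metric table, one row per class, eight metric columns."""
    rows = [metrics(class_counts(m, k)).as_tuple() for k in range(1, m.n_classes + 1)]
    return pd.DataFrame(rows, columns=list(METRIC_NAMES),
                        index=pd.RangeIndex(1, m.n_classes + 1, name="class"))


def mean_class_acc(m: ConfusionMatrix) -> float:
    """Unweighted mean of per-class ACC, skipping NaN entries."""
    return float(np.nanmean(metrics_table(m)["acc"].to_numpy()))


def overall_accuracy(m: ConfusionMatrix) -> float:
    return float(np.trace(m.counts) / m.total) if m.total else float("nan")


def pearson_significance(actual, estimated) -> tuple[float, float]:
    """Pearson r between actual and estimated codes with two-sided p.

    The p-value comes from t = r sqrt((n-2)/(1-r^2)) against Student's t
    with n-2 degrees of freedom (the textbook exact test under
    bivariate normality).
    """
    a = np.asarray(actual, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if a.shape != e.shape or a.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(a) == 0 or np.std(e) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(a, e)
    return float(res.statistic), float(res.pvalue)


def decision_surfaces(
    model: FISModel,
    X: np.ndarray,
    grid_size: int = 50,
    fixed_values: np.ndarray | None = None,
) -> dict[tuple[str, str], dict]:
    """Pairwise response surfaces over all C(6,2) = 15 input pairs.

    For each unordered pair of inputs a grid_size x grid_size grid spans
    the observed min..max of the two features while the remaining four
    are pinned at ``fixed_values`` (training means by default); each
    cell holds the crisp model output. Returned keys are feature-name
    pairs; values carry the two axes and the Z grid.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d = X.shape[1]
    fixed = X.mean(axis=0) if fixed_values is None else np.asarray(fixed_values, float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    names = model.feature_names
    surfaces: dict[tuple[str, str], dict] = {}
    for i, j in itertools.combinations(range(d), 2):
        gi = np.linspace(lo[i], hi[i], grid_size)
        gj = np.linspace(lo[j], hi[j], grid_size)
        GI, GJ = np.meshgrid(gi, gj, indexing="ij")
        probe = np.tile(fixed, (grid_size * grid_size, 1))
        probe[:, i] = GI.ravel()
        probe[:, j] = GJ.ravel()
        Z = evaluate_fis(model, probe).reshape(grid_size, grid_size)
        surfaces[(names[i], names[j])] = {"x": gi, "y": gj, "z": Z}
    return surfaces
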
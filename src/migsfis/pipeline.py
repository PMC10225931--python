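"""End-to-end training and evaluation pipeline.

clean -> normalize (inputs by absolute maximum) -> 60/40 split with a 5%
validation slice inside the training share -> subtractive clustering of
the joint input+output vectors -> one fuzzy rule per cluster -> hybrid
least-squares/gradient training -> rounded treatment advice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import anfis, classify, cohort, fuzzy, subclust
from .regression import RegressionModel, fit_regression, predict_regression


@dataclass
class EvalReport:
    """Test-set evaluation bundle for one classifier."""

    raw: np.ndarray
    predicted: np.ndarray
    confusion: classify.ConfusionMatrix
    accuracy: float
    mean_class_acc: float
    pearson_r: float
    pearson_p: float


def train_pipeline(
    data: cohort.Cohort,
    radius: float = 0.15,
    train_frac: float = 0.60,
    val_frac: float = 0.05,
    epochs: int = 50,
    seed: int = 0,
    subclust_params: subclust.SubclustParams | None = None,
    train_config: anfis.TrainConfig | None = None,
) -> tuple[fuzzy.FISModel, anfis.TrainingHistory, cohort.Cohort]:
    """Fit the fuzzy advisor on a labeled cohort; returns the held-out test set.

    Rule extraction clusters the joint 7-D (inputs, class code) vectors
    scaled to the unit box, so each cluster — and hence each rule —
    corresponds to a coherent feature-outcome pattern.
    """
    cleaned, _ = cohort.clean_cohort(data)
    if cleaned.size() == 0:
        raise ValueError("no usable rows after cleaning")
    train, val, test = cohort.split_cohort(cleaned, train_frac, val_frac, seed)
    norm = cohort.fit_normalizer(train)
    Xtr = norm.transform(train.features())
    ytr = train.labels()
    Xva = norm.transform(val.features()) if val.size() else None
    yva = val.labels() if val.size() else None

    params = subclust_params or subclust.SubclustParams(radius=radius)
    joint = np.column_stack([Xtr, ytr])
    scaled, box = subclust.scale_to_unit_box(joint)
    clusters = subclust.subtractive_cluster(scaled, params)

    model = fuzzy.build_fis(
        clusters, box, Xtr, ytr, radius=params.radius, normalizer=norm,
        meta={"seed": seed, "n_clusters": len(clusters)},
    )
    cfg = train_config or anfis.TrainConfig(epochs=epochs, seed=seed)
    model, history = anfis.train_anfis(model, Xtr, ytr, Xva, yva, cfg)
    return model, history, test


def predict(model: fuzzy.FISModel, data: cohort.Cohort) -> tuple[np.ndarray, np.ndarray]:
    """Raw crisp outputs and rounded treatment codes for a raw cohort."""
    if model.normalizer is None:
        raise ValueError("model carries no normalizer; cannot score raw cohorts")
    X = model.normalizer.transform(data.features())
    raw = fuzzy.evaluate_fis(model, X)
    return raw, classify.round_to_class(raw, model.n_classes)


def evaluate(model: fuzzy.FISModel, test: cohort.Cohort) -> EvalReport:
    raw, pred = predict(model, test)
    return _report(test.labels().astype(int), raw, pred, model.n_classes)


def evaluate_regression(
    reg: RegressionModel, test: cohort.Cohort, n_classes: int = 4
) -> EvalReport:
    raw, pred = predict_regression(reg, test.features(), n_classes)
    return _report(test.labels().astype(int), raw, pred, n_classes)


def _report(truth, raw, pred, n_classes) -> EvalReport:
    cm = classify.confusion(truth, pred, n_classes)
    if np.std(truth) > 0 and np.std(raw) > 0:
        r, p = classify.pearson_significance(truth, raw)
    else:
        r, p = float("nan"), float("nan")
    return EvalReport(
        raw=raw,
        predicted=pred,
        confusion=cm,
        accuracy=classify.overall_accuracy(cm),
        mean_class_acc=classify.mean_class_acc(cm),
        pearson_r=r,
        pearson_p=p,
    )


def compare_with_regression(
    data: cohort.Cohort, **pipeline_kw
) -> tuple[EvalReport, EvalReport]:
    """Fuzzy advisor vs. raw-feature regression on the same split."""
    model, _, test = train_pipeline(data, **pipeline_kw)
    cleaned, _ = cohort.clean_cohort(data)
    train, val, _ = cohort.split_cohort(
        cleaned,
        pipeline_kw.get("train_frac", 0.60),
        pipeline_kw.get("val_frac", 0.05),
        pipeline_kw.get("seed", 0),
    )
    reg_train = cohort.Cohort(pd.concat([train.df, val.df], ignore_index=True))
    reg = fit_regression(reg_train)
    return evaluate(model, test), evaluate_regression(reg, test)
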
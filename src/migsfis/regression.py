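"""Multiple-input linear-regression comparator.

Fits treatment category directly on the six raw (unnormalized) clinical
predictors with no intercept:

    TC = a1*Age + a2*VA + a3*VF + a4*IOP + a5*Drops + a6*Type

solved by the Moore-Penrose pseudoinverse, then classified with the same
rounding rule as the fuzzy system. This is the simplest credible
baseline a clinical-statistics reader would ask for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .classify import round_to_class
from .cohort import Cohort


@dataclass(frozen=True)
class RegressionModel:
    coefficients: np.ndarray  # six slopes, canonical feature order
    intercept: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", c)
        if c.shape != (6,) or not np.all(np.isfinite(c)):
            raise ValueError("need six finite coefficients")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"coefficients": self.coefficients.tolist(),
                 "intercept": self.intercept},
                fh, indent=1,
            )


def fit_regression(
    X: np.ndarray | Cohort,
    y: np.ndarray | None = None,
    intercept: bool = False,
) -> RegressionModel:
    """Minimum-norm least-squares coefficients via the pseudoinverse.

    Accepts either a labeled Cohort or an (X, y) pair. The residual is
    orthogonal to the column space of the design matrix; when columns
    are linearly dependent the pseudoinverse spreads weight minimally.
    """
    if isinstance(X, Cohort):
        y = X.labels()
        X = X.features()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) == 0:
        raise ValueError("cannot fit on an empty cohort")
    design = np.concatenate([X, np.ones((len(X), 1))], axis=1) if intercept else X
    a = np.linalg.pinv(design) @ y
    if intercept:
        return RegressionModel(coefficients=a[:-1], intercept=float(a[-1]))
    return RegressionModel(coefficients=a)


def predict_regression(
    model: RegressionModel, X: np.ndarray, n_classes: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Raw linear outputs and their rounded class codes."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    raw = X @ model.coefficients + model.intercept
    return raw, round_to_class(raw, n_classes)
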
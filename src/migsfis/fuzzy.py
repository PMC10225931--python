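"""First-order Takagi-Sugeno fuzzy inference with Gaussian premises.

A rule is "IF x_1 is A_1 AND ... AND x_6 is A_6 THEN y = p.x + r" where
each A_d is a Gaussian membership function. Firing strengths use the
product t-norm; the crisp output is the firing-strength-weighted average
of the rule consequents, i.e. the centroid of the implied output surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import FEATURE_NAMES, N_TREATMENT_CLASSES, NormalizationSpec
from .subclust import ClusterSet, UnitBox

SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class GaussianMF:
    center: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def mf_degree(mf: GaussianMF, x: float) -> float:
    """exp(-(x - c)^2 / (2 sigma^2)); 1 at the center, symmetric."""
    return float(np.exp(-((x - mf.center) ** 2) / (2.0 * mf.sigma**2)))


@dataclass(frozen=True)
class FuzzyRule:
    """One rule: six Gaussian premises and a linear consequent (p, r)."""

    premise: tuple[GaussianMF, ...]
    consequent: np.ndarray  # 7 reals: 6 slopes + bias


@dataclass
class FISModel:
    """A trained fuzzy system stored as dense per-rule parameter arrays.

    centers / sigmas are (R, 6) premise parameters in normalized feature
    units; consequents is (R, 7) with the bias last. The normalizer that
    produced the training scale travels with the model so prediction on
    raw cohorts reuses the training-time maxima.
    """

    centers: np.ndarray
    sigmas: np.ndarray
    consequents: np.ndarray
    normalizer: NormalizationSpec | None = None
    n_classes: int = N_TREATMENT_CLASSES
    feature_names: tuple[str, ...] = FEATURE_NAMES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        self.consequents = np.atleast_2d(np.asarray(self.consequents, dtype=float))
        r, d = self.centers.shape
        if r < 1:
            raise ValueError("a model needs at least one rule")
        if self.sigmas.shape != (r, d) or self.consequents.shape != (r, d + 1):
            raise ValueError("inconsistent rule parameter shapes")
        if not np.all(self.sigmas > 0):
            raise ValueError("all sigmas must be positive")

    @property
    def n_rules(self) -> int:
        return self.centers.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[1]

    @property
    def rules(self) -> list[FuzzyRule]:
        return [
            FuzzyRule(
                premise=tuple(
                    GaussianMF(float(c), float(s))
                    for c, s in zip(self.centers[k], self.sigmas[k])
                ),
                consequent=self.consequents[k].copy(),
            )
            for k in range(self.n_rules)
        ]

    def copy(self) -> "FISModel":
        return FISModel(
            centers=self.centers.copy(),
            sigmas=self.sigmas.copy(),
            consequents=self.consequents.copy(),
            normalizer=self.normalizer,
            n_classes=self.n_classes,
            feature_names=self.feature_names,
            meta=dict(self.meta),
        )

    # -- serialization: JSON at full double precision ------------------

    def to_dict(self) -> dict:
        return {
            "meta": self.meta,
            "n_classes": self.n_classes,
            "feature_names": list(self.feature_names),
            "normalizer": self.normalizer.to_dict() if self.normalizer else None,
            "rules": [
                {
                    "premise": [
                        {"center": float(c), "sigma": float(s)}
                        for c, s in zip(self.centers[k], self.sigmas[k])
                    ],
                    "consequent": [float(v) for v in self.consequents[k]],
                }
                for k in range(self.n_rules)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FISModel":
        rules = d["rules"]
        centers = np.array([[m["center"] for m in r["premise"]] for r in rules])
        sigmas = np.array([[m["sigma"] for m in r["premise"]] for r in rules])
        consequents = np.array([r["consequent"] for r in rules])
        norm = d.get("normalizer")
        return cls(
            centers=centers,
            sigmas=sigmas,
            consequents=consequents,
            normalizer=NormalizationSpec.from_dict(norm) if norm else None,
            n_classes=int(d.get("n_classes", N_TREATMENT_CLASSES)),
            feature_names=tuple(d.get("feature_names", FEATURE_NAMES)),
            meta=dict(d.get("meta", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FISModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def rule_firing(model: FISModel, X: np.ndarray) -> np.ndarray:
    """Product-t-norm firing strengths, shape (N, R); all entries in (0, 1]."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    z = (X[:, None, :] - model.centers[None, :, :]) / model.sigmas[None, :, :]
    return np.exp(-0.5 * (z**2).sum(axis=2))


def evaluate_fis(model: FISModel, X: np.ndarray) -> np.ndarray:
    """Weighted-average defuzzified output, one crisp value per row.

    The output is a convex combination of the rule consequent values, so
    it always lies within their pointwise min/max envelope.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w = rule_firing(model, X)
    s = w.sum(axis=1)
    if np.any(s < 1e-300):
        raise FloatingPointError("degenerate firing: all rule strengths underflowed")
    f = X @ model.consequents[:, :-1].T + model.consequents[:, -1]
    return (w * f).sum(axis=1) / s


def build_fis(
    clusters: ClusterSet,
    box: UnitBox,
    X: np.ndarray,
    y: np.ndarray,
    radius: float,
    normalizer: NormalizationSpec | None = None,
    constant_consequents: bool = False,
    meta: dict | None = None,
) -> FISModel:
    """One rule per cluster; consequents from the global least-squares solve.

    ``clusters`` lives in the unit box over the joint (input, output)
    space; its centers are mapped back and the first ``X.shape[1]``
    coordinates become the premise centers. Each premise width follows
    the classical radius-to-sigma conversion
    ``sigma_d = radius * (max_d - min_d) / sqrt(8)`` on the training data
    range (floored at 1e-6 for degenerate dimensions).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) == 0:
        raise ValueError("empty training matrix")
    d = X.shape[1]
    joint_centers = box.inverse(clusters.centers)
    centers = joint_centers[:, :d]
    span = X.max(axis=0) - X.min(axis=0)
    sigma = np.maximum(radius * span / np.sqrt(8.0), SIGMA_FLOOR)
    sigmas = np.tile(sigma, (len(centers), 1))
    consequents = np.zeros((len(centers), d + 1))
    model = FISModel(
        centers=centers,
        sigmas=sigmas,
        consequents=consequents,
        normalizer=normalizer,
        meta=dict(meta or {}),
    )
    model.meta.setdefault("radius", float(radius))
    model.meta["constant_consequents"] = bool(constant_consequents)
    from .anfis import lse_consequents  # deferred: anfis imports this module

    return lse_consequents(model, X, y)
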
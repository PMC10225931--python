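"""Synthetic glaucoma-cohort generator.

Emulates the joint shape of a single-center MIGS audit cohort: continuous
features follow truncated normals matching the audit's published
means/SDs, values are quantized to clinical measurement precision (whole
years and mmHg, 0.1-LogMAR and 0.1-dB steps), disease-severity markers
(IOP, visual-field loss, drop count) are mutually correlated through a
Gaussian copula, and treatment labels follow a planted first-match
rulebook, optionally corrupted by label noise. The planted structure is
deliberately recoverable by a local classifier: its class boundaries sit
on the coarse discrete features (glaucoma-type code, drop count), whose
unit steps carry real distance in the normalized feature space, and the
correlated severity block makes each class region coherent across several
features at once — the joint-density clumping real clinical tables show.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FEATURE_NAMES, LABEL_NAME, N_TREATMENT_CLASSES, Cohort


@dataclass(frozen=True)
class Marginal:
    """Truncated-normal parameters (mean, sd) on [lo, hi].

    ``step`` quantizes draws to the feature's clinical measurement
    precision (0 disables quantization).
    """

    mean: float
    sd: float
    lo: float
    hi: float
    step: float = 0.0

    def __post_init__(self) -> None:
        if self.hi < self.lo:
            raise ValueError("hi must be >= lo")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.step < 0:
            raise ValueError("step must be >= 0")


#: Audit-cohort marginals: mean +/- sd with the observed absolute maximum
#: as the upper truncation bound and a clinically sensible lower bound.
DEFAULT_MARGINALS: dict[str, Marginal] = {
    "age": Marginal(77.36, 3.819, 40.0, 97.0, step=1.0),
    "va": Marginal(0.3, 0.25, 0.0, 1.4, step=0.1),
    "iop": Marginal(18.54, 4.62, 6.0, 40.0, step=1.0),
    "vf": Marginal(-7.65, 7.2, -33.0, 1.11, step=0.1),
    "drops": Marginal(2.12, 1.08, 0.0, 5.0, step=1.0),
}

_COPULA_ORDER = ("age", "va", "iop", "vf", "drops")

#: Severity-block correlations (Gaussian-copula scale, feature order
#: age, va, iop, vf, drops): pressure, medication burden and field loss
#: rise and fall together, acuity worsens with field loss, age weakly
#: tracks both. Pass identity to draw features independently.
DEFAULT_CORRELATION = np.array(
    [
        # age    va    iop    vf   drops
        [1.00,  0.30,  0.00, -0.20,  0.00],   # age
        [0.30,  1.00,  0.00, -0.50,  0.00],   # va (higher = worse)
        [0.00,  0.00,  1.00, -0.70,  0.85],   # iop
        [-0.20, -0.50, -0.70, 1.00, -0.75],   # vf (lower = worse)
        [0.00,  0.00,  0.85, -0.75,  1.00],   # drops
    ]
)

#: Uniform glaucoma-type mix (default) and a preset skewed toward the
#: open-angle codes 5-6 whose mean matches the audit's reported 5.13.
GTYPE_UNIFORM = np.full(6, 1 / 6)
GTYPE_SKEWED = np.array([0.02, 0.03, 0.05, 0.10, 0.30, 0.50])

_OPS = {">": operator.gt, "<": operator.lt, ">=": operator.ge, "<=": operator.le}


@dataclass(frozen=True)
class Rule:
    """One planted predicate: ``feature op threshold -> klass``."""

    feature: str
    op: str
    threshold: float
    klass: int

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.op not in _OPS:
            raise ValueError(f"unknown operator {self.op!r}")
        if not 1 <= self.klass <= N_TREATMENT_CLASSES:
            raise ValueError("class outside 1..4")

    def matches(self, values: np.ndarray) -> np.ndarray:
        return _OPS[self.op](values, self.threshold)


@dataclass(frozen=True)
class Rulebook:
    """Ordered first-match rules with a default class (hence exhaustive)."""

    rules: tuple[Rule, ...]
    default_class: int = 3

    def assign(self, df: pd.DataFrame) -> np.ndarray:
        labels = np.full(len(df), self.default_class, dtype=int)
        unset = np.ones(len(df), dtype=bool)
        for rule in self.rules:
            hit = unset & rule.matches(df[rule.feature].to_numpy(dtype=float))
            labels[hit] = rule.klass
            unset &= ~hit
        return labels


def default_rulebook() -> Rulebook:
    """Treatment keyed on glaucoma-type group, split by medication burden.

    Angle-closure-spectrum types (codes 1-2) get combined stent+ECP
    surgery (class 1); open-angle types (codes 5-6) get the iStent
    (class 4); the middle types go to the MicroShunt (class 2) when
    already on three or more drops, otherwise to XEN (class 3). Class
    codes are assigned so that regions adjacent in feature space mostly
    carry adjacent codes, and every class keeps a non-trivial prevalence
    under the default marginals.
    """
    return Rulebook(
        rules=(
            Rule("gtype", "<=", 2, 1),
            Rule("gtype", ">=", 5, 4),
            Rule("drops", ">=", 3, 2),
        ),
        default_class=3,
    )


@dataclass(frozen=True)
class SyntheticConfig:
    n: int = 372
    seed: int = 0
    marginals: dict[str, Marginal] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    correlation: np.ndarray = field(default_factory=lambda: DEFAULT_CORRELATION.copy())
    gtype_probs: np.ndarray = field(default_factory=lambda: GTYPE_UNIFORM.copy())
    label_noise: float = 0.0
    rulebook: Rulebook = field(default_factory=default_rulebook)
    labeled: bool = True

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")
        p = np.asarray(self.gtype_probs, dtype=float)
        if p.shape != (6,) or not np.isclose(p.sum(), 1.0) or (p < 0).any():
            raise ValueError("gtype_probs must be six nonnegative values summing to 1")
        object.__setattr__(self, "gtype_probs", p)
        missing = [f for f in DEFAULT_MARGINALS if f not in self.marginals]
        if missing:
            raise ValueError(f"marginals missing for: {missing}")
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (5, 5) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
            raise ValueError("correlation must be a symmetric 5x5 matrix with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")
        object.__setattr__(self, "correlation", R)

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


def _truncnorm(m: Marginal):
    a = (m.lo - m.mean) / m.sd
    b = (m.hi - m.mean) / m.sd
    return stats.truncnorm(a, b, loc=m.mean, scale=m.sd)


def generate_cohort(cfg: SyntheticConfig) -> Cohort:
    """Draw a cohort under the configured joint model and planted rules.

    Continuous features come from a Gaussian copula (correlation matrix
    over age, va, iop, vf, drops) pushed through each truncated-normal
    marginal, then snapped to the feature's measurement step. Drop
    counts become integers within range. Labels are the first matching
    rulebook predicate, replaced with a uniform random class with
    probability ``label_noise``. The same seed always yields the
    identical cohort.
    """
    rng = np.random.default_rng(cfg.seed)
    chol = np.linalg.cholesky(cfg.correlation)
    z = rng.standard_normal((cfg.n, len(_COPULA_ORDER))) @ chol.T
    u = stats.norm.cdf(z)

    data = {}
    for k, name in enumerate(_COPULA_ORDER):
        m = cfg.marginals[name]
        v = _truncnorm(m).ppf(u[:, k])
        if m.step > 0:
            v = np.clip(np.round(v / m.step) * m.step, m.lo, m.hi)
        data[name] = v
    m = cfg.marginals["drops"]
    data["drops"] = np.clip(
        np.round(data["drops"]), np.ceil(m.lo), np.floor(m.hi)
    ).astype(int)
    data["gtype"] = rng.choice(np.arange(1, 7), size=cfg.n, p=cfg.gtype_probs)
    df = pd.DataFrame(data, columns=list(FEATURE_NAMES))

    if cfg.labeled:
        labels = cfg.rulebook.assign(df)
        if cfg.label_noise > 0:
            flip = rng.random(cfg.n) < cfg.label_noise
            labels[flip] = rng.integers(1, N_TREATMENT_CLASSES + 1, size=int(flip.sum()))
        df[LABEL_NAME] = labels
    return Cohort(df)
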
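"""Hybrid ANFIS training.

Each epoch alternates an exact global least-squares solve of all linear
consequent coefficients (with the premises frozen) against a batch
gradient-descent update of the Gaussian premise centers and widths. A
small validation slice is scored every epoch and the checkpoint with the
lowest validation RMSE is returned, which caps over-fitting without a
convergence tolerance. Training regresses directly onto the integer class
codes 1..4; rounding to a class happens downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .fuzzy import SIGMA_FLOOR, FISModel, evaluate_fis, rule_firing


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the hybrid schedule.

    The step size is the Euclidean length of each premise update (the
    gradient only supplies the direction). It grows by ``step_increase``
    after four consecutive training-error decreases and shrinks by
    ``step_decrease`` after two consecutive up-down oscillations — the
    classical ANFIS step-size heuristic.
    """

    epochs: int = 50
    initial_step: float = 0.01
    step_increase: float = 1.1
    step_decrease: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")
        if self.step_increase <= 1:
            raise ValueError("step_increase must exceed 1")
        if not 0 < self.step_decrease < 1:
            raise ValueError("step_decrease must be in (0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch RMSE trace; best_epoch is the validation argmin."""

    train_rmse: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    step: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "train_rmse", "val_rmse", "step"])
            for i, (tr, va, st) in enumerate(
                zip(self.train_rmse, self.val_rmse, self.step)
            ):
                w.writerow([i, repr(tr), "" if np.isnan(va) else repr(va), repr(st)])


def _rmse(model: FISModel, X: np.ndarray, y: np.ndarray) -> float:
    if len(X) == 0:
        return float("nan")
    e = evaluate_fis(model, X) - y
    return float(np.sqrt(np.mean(e**2)))


def lse_consequents(model: FISModel, X: np.ndarray, y: np.ndarray) -> FISModel:
    """Globally optimal consequents for fixed premises.

    With normalized firing strengths w_c/sum(w) as per-rule mixing
    weights, the defuzzified output is linear in the R*(d+1) consequent
    coefficients, so one minimum-norm least-squares solve fits them all
    simultaneously. Training SSE never increases relative to the
    incoming coefficients.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if len(X) == 0:
        raise ValueError("need at least one training row")
    n, d = X.shape
    w = rule_firing(model, X)
    wn = w / w.sum(axis=1, keepdims=True)
    constant = bool(model.meta.get("constant_consequents", False))
    out = model.copy()
    if constant:
        sol, *_ = np.linalg.lstsq(wn, y, rcond=None)
        out.consequents[:, :-1] = 0.0
        out.consequents[:, -1] = sol
    else:
        xb = np.concatenate([X, np.ones((n, 1))], axis=1)  # (n, d+1)
        phi = (wn[:, :, None] * xb[:, None, :]).reshape(n, -1)
        sol, *_ = np.linalg.lstsq(phi, y, rcond=None)
        out.consequents = sol.reshape(model.n_rules, d + 1)
    return out


def _premise_gradients(
    model: FISModel, X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic d(SSE)/d(centers), d(SSE)/d(sigmas), shapes (R, d)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    w = rule_firing(model, X)  # (n, R)
    # floor against total underflow far from every rule: such samples then
    # contribute zero gradient instead of 0/0
    s = np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
    f = X @ model.consequents[:, :-1].T + model.consequents[:, -1]  # (n, R)
    yhat = (w * f).sum(axis=1) / s[:, 0]
    # dE/dw_c = 2 e (f_c - yhat) / s ; dw/dc, dw/dsigma from the Gaussian.
    a = (2.0 * (yhat - y))[:, None] * (f - yhat[:, None]) * w / s  # (n, R)
    diff = X[:, None, :] - model.centers[None, :, :]  # (n, R, d)
    inv_s2 = 1.0 / model.sigmas**2
    g_centers = np.einsum("nr,nrd->rd", a, diff) * inv_s2
    g_sigmas = np.einsum("nr,nrd->rd", a, diff**2) * inv_s2 / model.sigmas
    return g_centers, g_sigmas


def premise_gradient_step(
    model: FISModel, X: np.ndarray, y: np.ndarray, step: float
) -> FISModel:
    """One batch update of every premise center and sigma against SSE.

    The update moves the stacked parameter vector a distance ``step``
    along the negative normalized gradient; sigmas are clamped at 1e-6.
    ``step = 0`` (or a zero gradient at an exact optimum) leaves the
    model unchanged.
    """
    if step < 0:
        raise ValueError("step must be nonnegative")
    out = model.copy()
    if step == 0:
        return out
    g_c, g_s = _premise_gradients(model, X, y)
    norm = float(np.sqrt((g_c**2).sum() + (g_s**2).sum()))
    if norm == 0.0:
        return out
    out.centers = model.centers - step * g_c / norm
    out.sigmas = np.maximum(model.sigmas - step * g_s / norm, SIGMA_FLOOR)
    return out


class _StepScheduler:
    """Classical ANFIS step heuristic with counter resets.

    Grow the step after four consecutive training-error decreases;
    shrink it after two consecutive up-down oscillations (four
    alternating error deltas). Each adjustment resets its counter.
    """

    def __init__(self, cfg: TrainConfig) -> None:
        self.cfg = cfg
        self.prev_err: float | None = None
        self.prev_delta: float = 0.0
        self.dec_run = 0
        self.alt_run = 0

    def update(self, step: float, err: float) -> float:
        if self.prev_err is None:
            self.prev_err = err
            return step
        delta = err - self.prev_err
        self.prev_err = err
        self.dec_run = self.dec_run + 1 if delta < 0 else 0
        if delta * self.prev_delta < 0:
            self.alt_run += 1
        else:
            self.alt_run = 0
        self.prev_delta = delta
        if self.dec_run >= 4:
            self.dec_run = 0
            return step * self.cfg.step_increase
        if self.alt_run >= 3:
            self.alt_run = 0
            return step * self.cfg.step_decrease
        return step


def train_anfis(
    model: FISModel,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    config: TrainConfig | None = None,
) -> tuple[FISModel, TrainingHistory]:
    """Hybrid training loop returning the best validation checkpoint.

    Epoch 0 is the pure least-squares initialization (no premise
    update), so ``epochs=0`` reproduces build + consequent solve
    exactly. With no validation rows the last epoch is returned.
    """
    cfg = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    has_val = X_val is not None and len(np.atleast_2d(X_val)) > 0
    if has_val:
        X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
        y_val = np.asarray(y_val, dtype=float)

    hist = TrainingHistory()
    step = cfg.initial_step
    sched = _StepScheduler(cfg)

    model = lse_consequents(model, X, y)
    best = model.copy()
    best_val = np.inf

    for epoch in range(cfg.epochs + 1):
        tr = _rmse(model, X, y)
        va = _rmse(model, X_val, y_val) if has_val else float("nan")
        hist.train_rmse.append(tr)
        hist.val_rmse.append(va)
        hist.step.append(step)
        crit = va if has_val else np.inf
        if crit < best_val:
            best_val = crit
            hist.best_epoch = epoch
            best = model.copy()
        if epoch == cfg.epochs:
            break
        step = sched.update(step, tr)
        model = premise_gradient_step(model, X, y, step)
        model = lse_consequents(model, X, y)

    if not has_val:
        best = model
        hist.best_epoch = len(hist.train_rmse) - 1
    best.meta["epochs_trained"] = cfg.epochs
    best.meta["best_epoch"] = hist.best_epoch
    return best, hist
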
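"""Subtractive clustering for fuzzy-rule extraction.

Each data point starts with a "potential" measuring how densely it is
surrounded; the highest-potential point becomes a cluster center, its
neighborhood's potential is subtracted away, and the loop repeats until
remaining potentials drop below thresholds. One user-facing knob — the
radius of influence — controls neighborhood size and hence the number of
rules the downstream fuzzy system gets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class SubclustParams:
    """Radius of influence plus the classical acceptance thresholds.

    radius
        Neighborhood radius r_a in unit-box coordinates. Smaller radii
        yield more, finer clusters; the default 0.15 gives roughly one
        rule per two training samples on a cohort-sized input.
    squash
        Ratio r_b/r_a of the subtraction radius to the cluster radius;
        > 1 keeps new centers away from existing ones.
    accept_ratio / reject_ratio
        Fractions of the first center's potential above which a candidate
        is accepted outright resp. below which selection stops.
    """

    radius: float = 0.15
    squash: float = 1.25
    accept_ratio: float = 0.5
    reject_ratio: float = 0.15

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.squash <= 1:
            raise ValueError("squash must exceed 1")
        if not 0 < self.reject_ratio < self.accept_ratio < 1:
            raise ValueError("need 0 < reject_ratio < accept_ratio < 1")


@dataclass(frozen=True)
class UnitBox:
    """Per-dimension (min, max) of the affine map onto [0, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        out = np.asarray(scaled, dtype=float) * span + self.lo
        const = span == 0
        if const.any():
            out[..., const] = self.lo[const]
        return out


@dataclass
class ClusterSet:
    """Selected centers (each one an input point) in selection order."""

    centers: np.ndarray  # (k, d), unit-box coordinates
    potentials: np.ndarray = field(default=None)  # potential at selection
    indices: np.ndarray = field(default=None)  # row index of each center

    def __len__(self) -> int:
        return len(self.centers)


def scale_to_unit_box(points: np.ndarray) -> tuple[np.ndarray, UnitBox]:
    """Affinely map each dimension onto [0, 1]; constant dims map to 0.5."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("no points to scale")
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    span = hi - lo
    const = span == 0
    safe = np.where(const, 1.0, span)
    scaled = (pts - lo) / safe
    scaled[:, const] = 0.5
    return scaled, UnitBox(lo=lo, hi=hi)


def compute_potentials(points: np.ndarray, radius: float) -> np.ndarray:
    """P_i = sum_j exp(-alpha ||x_i - x_j||^2), alpha = 4 / radius^2."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    alpha = 4.0 / radius**2
    sq = cdist(pts, pts, "sqeuclidean")
    return np.exp(-alpha * sq).sum(axis=1)


def subtractive_cluster(points: np.ndarray, params: SubclustParams) -> ClusterSet:
    """Iterative max-potential center selection with potential subtraction.

    After each accepted center k the revised potential is
    ``P_i <- P_i - P_k exp(-beta ||x_i - x_k||^2)`` with
    ``beta = 4 / (squash * radius)^2``. A candidate whose potential falls
    between the accept and reject thresholds is kept only if it is far
    enough from existing centers: ``d_min/radius + P/P_1 >= 1``; otherwise
    its potential is zeroed and selection continues. Ties break to the
    lowest row index. Always returns at least one center.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n == 0:
        raise ValueError("no points to cluster")
    beta = 4.0 / (params.squash * params.radius) ** 2
    pot = compute_potentials(pts, params.radius)

    centers: list[int] = []
    selected_pot: list[float] = []

    def accept(idx: int, p: float) -> None:
        centers.append(idx)
        selected_pot.append(p)
        sq = ((pts - pts[idx]) ** 2).sum(axis=1)
        pot_local = pot
        pot_local -= p * np.exp(-beta * sq)

    first = int(np.argmax(pot))  # argmax takes the lowest index on ties
    p_first = float(pot[first])
    accept(first, p_first)

    while len(centers) < n:
        idx = int(np.argmax(pot))
        p = float(pot[idx])
        if p >= params.accept_ratio * p_first:
            accept(idx, p)
        elif p < params.reject_ratio * p_first:
            break
        else:
            d_min = np.sqrt(
                ((pts[idx] - pts[centers]) ** 2).sum(axis=1).min()
            )
            if d_min / params.radius + p / p_first >= 1.0:
                accept(idx, p)
            else:
                pot[idx] = 0.0

    order = np.asarray(centers, dtype=int)
    return ClusterSet(
        centers=pts[order].copy(),
        potentials=np.asarray(selected_pot, dtype=float),
        indices=order,
    )
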
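"""Patient-cohort data model: loading, cleaning, normalization, splitting.

A cohort is a table with one row per glaucoma patient and six baseline
predictors — age (years), best-corrected visual acuity (LogMAR),
intraocular pressure (mmHg), visual-field mean deviation (dB), number of
daily IOP-lowering drops, and a glaucoma-type code in 1..6 — plus an
optional treatment-category label in 1..4 (the MIGS procedure performed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical predictor column order; the label column is ``treatment``.
FEATURE_NAMES: tuple[str, ...] = ("age", "va", "iop", "vf", "drops", "gtype")
LABEL_NAME = "treatment"

N_GLAUCOMA_TYPES = 6
N_TREATMENT_CLASSES = 4


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A cell failed to parse as a number."""


@dataclass(frozen=True)
class PatientRecord:
    """One six-feature observation with an optional treatment label."""

    age: float
    va: float
    iop: float
    vf: float
    drops: float
    gtype: int
    treatment: int | None = None

    def features(self) -> np.ndarray:
        return np.array(
            [self.age, self.va, self.iop, self.vf, self.drops, self.gtype],
            dtype=float,
        )


@dataclass
class Cohort:
    """An ordered collection of patient records backed by a DataFrame.

    Row order is identity: all operations preserve it, and the split is a
    permutation of positional indices.
    """

    df: pd.DataFrame
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        missing = [c for c in self.feature_names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"cohort table lacks feature columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    @property
    def labeled(self) -> bool:
        return LABEL_NAME in self.df.columns

    def size(self) -> int:
        return len(self.df)

    def features(self) -> np.ndarray:
        """N x 6 float matrix of predictors in canonical order."""
        return self.df.loc[:, list(self.feature_names)].to_numpy(dtype=float)

    def labels(self) -> np.ndarray:
        if not self.labeled:
            raise SchemaError("cohort is unlabeled: no treatment column")
        return self.df[LABEL_NAME].to_numpy(dtype=float)

    def records(self) -> list[PatientRecord]:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                PatientRecord(
                    age=float(row["age"]),
                    va=float(row["va"]),
                    iop=float(row["iop"]),
                    vf=float(row["vf"]),
                    drops=float(row["drops"]),
                    gtype=int(row["gtype"]),
                    treatment=int(row[LABEL_NAME]) if self.labeled else None,
                )
            )
        return out

    def take(self, idx: np.ndarray) -> "Cohort":
        return Cohort(self.df.iloc[np.asarray(idx, dtype=int)].reset_index(drop=True))

    def with_features(self, X: np.ndarray) -> "Cohort":
        """Copy of the cohort with the predictor block replaced by ``X``."""
        df = self.df.copy()
        X = np.asarray(X, dtype=float)
        for i, name in enumerate(self.feature_names):
            df[name] = X[:, i]
        return Cohort(df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-feature absolute maxima; normalization divides by them.

    Only the inputs are scaled (each feature into [-1, 1] on the fitting
    cohort); treatment codes stay on their native 1..4 scale. Variances are
    deliberately not standardized.
    """

    abs_max: np.ndarray

    def __post_init__(self) -> None:
        am = np.asarray(self.abs_max, dtype=float)
        object.__setattr__(self, "abs_max", am)
        if am.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"abs_max must have {len(FEATURE_NAMES)} entries")
        if not np.all(am > 0):
            raise ValueError("all abs_max entries must be positive")

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) / self.abs_max

    def inverse(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.abs_max

    def to_dict(self) -> dict:
        return {"abs_max": [float(v) for v in self.abs_max]}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(abs_max=np.asarray(d["abs_max"], dtype=float))


def load_cohort(path, schema: dict[str, str] | None = None) -> Cohort:
    """Read a cohort CSV (comma-separated, header row, '.' decimal).

    ``schema`` maps canonical names to the file's column names, e.g.
    ``{"age": "Age (years)"}``; unmapped names are taken verbatim. A file
    without a treatment column loads as an unlabeled cohort.
    """
    raw = pd.read_csv(path)
    schema = schema or {}
    cols = {}
    for name in FEATURE_NAMES:
        src = schema.get(name, name)
        if src not in raw.columns:
            raise SchemaError(f"column {src!r} (for feature {name!r}) not in {path}")
        cols[name] = src
    label_src = schema.get(LABEL_NAME, LABEL_NAME)
    if label_src in raw.columns:
        cols[LABEL_NAME] = label_src

    data = {}
    for name, src in cols.items():
        col = pd.to_numeric(raw[src], errors="coerce")
        bad = col.isna() & raw[src].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {raw[src].iloc[row]!r} at row {row}, column {name!r}"
            )
        data[name] = col
    return Cohort(pd.DataFrame(data))


def clean_cohort(c: Cohort) -> tuple[Cohort, int]:
    """Drop incomplete or out-of-code rows; returns (cohort, n_dropped).

    A row is dropped when any field is missing/non-finite, gtype falls
    outside 1..6, or a present treatment label falls outside 1..4. Rows are
    dropped, never imputed.
    """
    df = c.df
    vals = df.loc[:, list(c.feature_names)].to_numpy(dtype=float)
    keep = np.isfinite(vals).all(axis=1)
    gtype = df["gtype"].to_numpy(dtype=float)
    keep &= np.isin(gtype, np.arange(1, N_GLAUCOMA_TYPES + 1))
    if c.labeled:
        t = df[LABEL_NAME].to_numpy(dtype=float)
        keep &= np.isfinite(t) & np.isin(t, np.arange(1, N_TREATMENT_CLASSES + 1))
    cleaned = Cohort(df.loc[keep].reset_index(drop=True))
    return cleaned, int((~keep).sum())


def fit_normalizer(c: Cohort) -> NormalizationSpec:
    """Largest absolute value per feature on the given cohort."""
    if c.size() == 0:
        raise ValueError("cannot fit a normalizer on an empty cohort")
    abs_max = np.abs(c.features()).max(axis=0)
    zero = abs_max <= 0
    if zero.any():
        names = [c.feature_names[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"degenerate all-zero feature column(s): {names}")
    return NormalizationSpec(abs_max=abs_max)


def apply_normalizer(c: Cohort, spec: NormalizationSpec) -> Cohort:
    """Divide each predictor by its absolute maximum; labels untouched.

    Values may leave [-1, 1] when the cohort exceeds the fitting maxima
    (e.g. a test set); no clipping is applied.
    """
    return c.with_features(spec.transform(c.features()))


def split_cohort(
    c: Cohort,
    train_frac: float = 0.60,
    val_frac_of_train: float = 0.05,
    seed: int = 0,
) -> tuple[Cohort, Cohort, Cohort]:
    """Random disjoint (train, val, test) partition, reproducible by seed.

    The validation share is carved from inside the training fraction:
    ``n_train_total = round(train_frac * N)``,
    ``n_val = floor(val_frac_of_train * n_train_total)``, test gets the
    remainder. Same seed, same cohort => identical index partition.
    """
    if not 0 < train_frac < 1:
        raise ValueError(f"train_frac must be in (0, 1), got {train_frac}")
    if not 0 <= val_frac_of_train < 1:
        raise ValueError(f"val_frac_of_train must be in [0, 1), got {val_frac_of_train}")
    n = c.size()
    n_train_total = int(np.floor(train_frac * n + 0.5))
    n_val = int(np.floor(val_frac_of_train * n_train_total))
    n_train = n_train_total - n_val
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return (
        c.take(perm[:n_train]),
        c.take(perm[n_train:n_train_total]),
        c.take(perm[n_train_total:]),
    )
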
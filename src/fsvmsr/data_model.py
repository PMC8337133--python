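"""Dataset container, CSV I/O, risk-level grouping schemes, standardization,
and the geriatric nutritional risk index (GNRI).

The central object is :class:`Dataset`: an N x d numeric feature matrix with
integer labels (either ordinal vascular-calcification risk levels 0-6, or
class indices >= 1 after a :class:`GroupingScheme` has been applied).

Feature scales in dialysis cohorts span several orders of magnitude (serum
fetuin-A ~3e5 pg/mL next to serum calcium ~2 mmol/L), so z-score
standardization — fitted on training rows only — precedes every
kernel/self-representation computation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DimensionMismatchError,
    MissingLabelColumnError,
    MissingValueError,
    NonNumericFeatureError,
    TooFewSamplesError,
    UnknownLevelError,
    InvalidParameterError,
)

__all__ = [
    "Dataset",
    "GroupingScheme",
    "CS1",
    "CS2",
    "Standardizer",
    "GNRIInputs",
    "load_dataset",
    "save_dataset",
    "apply_scheme",
    "fit_standardizer",
    "gnri",
]


@dataclass(frozen=True)
class Dataset:
    """Immutable sample table: features (N x d), labels (N,), feature names."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self):
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if X.ndim != 2:
            raise DimensionMismatchError("features must be a 2-D matrix")
        if X.shape[0] < 2:
            raise TooFewSamplesError(f"need N >= 2 samples, got {X.shape[0]}")
        if X.shape[1] < 1:
            raise DimensionMismatchError("need at least one feature column")
        if len(self.feature_names) != X.shape[1]:
            raise DimensionMismatchError(
                f"{len(self.feature_names)} names for {X.shape[1]} columns"
            )
        if y.shape != (X.shape[0],):
            raise DimensionMismatchError("labels length must equal sample count")
        if np.any(y < 0):
            raise InvalidParameterError("labels must be non-negative integers")
        if not np.all(np.isfinite(X)):
            raise MissingValueError("features contain non-finite values")

    @property
    def N(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def with_labels(self, labels: np.ndarray) -> "Dataset":
        return Dataset(self.features, labels, self.feature_names)

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(self.features[idx], self.labels[idx], self.feature_names)


@dataclass(frozen=True)
class GroupingScheme:
    """Total map from ordinal risk levels to contiguous class indices 1..c."""

    name: str
    level_to_class: dict[int, int]

    def __post_init__(self):
        classes = sorted(set(self.level_to_class.values()))
        if classes != list(range(1, len(classes) + 1)):
            raise InvalidParameterError(
                f"scheme {self.name!r}: class indices must be contiguous from 1, "
                f"got {classes}"
            )

    @property
    def c(self) -> int:
        return len(set(self.level_to_class.values()))


#: two-class scheme: levels {0,1,2} -> class 1, {3,4,5,6} -> class 2
CS1 = GroupingScheme("CS1", {0: 1, 1: 1, 2: 1, 3: 2, 4: 2, 5: 2, 6: 2})
#: three-class scheme: {0,1} -> 1, {2,3} -> 2, {4,5,6} -> 3
CS2 = GroupingScheme("CS2", {0: 1, 1: 1, 2: 2, 3: 2, 4: 3, 5: 3, 6: 3})

BUILTIN_SCHEMES = {"CS1": CS1, "CS2": CS2}


def apply_scheme(levels, scheme: GroupingScheme) -> np.ndarray:
    """Map a vector of risk levels elementwise to class indices in 1..c."""
    levels = np.asarray(levels, dtype=int)
    out = np.empty_like(levels)
    for i, lv in enumerate(levels.ravel()):
        if int(lv) not in scheme.level_to_class:
            raise UnknownLevelError(
                f"level {lv} not in domain of scheme {scheme.name!r}"
            )
        out.ravel()[i] = scheme.level_to_class[int(lv)]
    return out


def load_dataset(path, label_column: str, impute_mean: bool = False) -> Dataset:
    """Read a header CSV into a :class:`Dataset`.

    All non-label columns are feature columns and must be numeric
    (yes/no categoricals are expected pre-encoded as 0/1). Missing cells
    are rejected with a precise row/column message unless ``impute_mean``
    is set, in which case they are replaced by the column mean.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise MissingLabelColumnError(
            f"label column {label_column!r} not found; columns: {list(df.columns)}"
        )
    feat_cols = [c for c in df.columns if c != label_column]
    X = np.empty((len(df), len(feat_cols)), dtype=float)
    for j, col in enumerate(feat_cols):
        vals = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = np.isnan(vals)
        if bad.any():
            row = int(np.argmax(bad))
            raw = df[col].iloc[row]
            if pd.isna(raw):
                if impute_mean:
                    vals[bad] = np.nanmean(vals) if not np.all(bad) else 0.0
                else:
                    raise MissingValueError(
                        f"missing value at row {row}, column {col!r}"
                    )
            else:
                raise NonNumericFeatureError(
                    f"non-numeric value {raw!r} at row {row}, column {col!r}"
                )
        X[:, j] = vals
    labels = pd.to_numeric(df[label_column], errors="coerce").to_numpy()
    if np.isnan(labels).any():
        row = int(np.argmax(np.isnan(labels)))
        raise NonNumericFeatureError(
            f"non-numeric label at row {row}, column {label_column!r}"
        )
    if len(df) < 2:
        raise TooFewSamplesError(f"need N >= 2 rows, got {len(df)}")
    return Dataset(X, labels.astype(int), tuple(feat_cols))


def save_dataset(dataset: Dataset, path, label_column: str = "label") -> None:
    """Write a Dataset back to CSV (inverse of :func:`load_dataset`).

    Uses repr-roundtrip float formatting so load -> save -> load is
    bit-exact for finite values.
    """
    df = pd.DataFrame(dataset.features, columns=list(dataset.feature_names))
    df[label_column] = dataset.labels
    df.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-score parameters fitted on training rows only.

    Zero-variance features get SD replaced by 1 so they transform to 0
    rather than NaN.
    """

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.mean.shape[0]:
            raise DimensionMismatchError(
                f"standardizer fitted on d={self.mean.shape[0]}, got d={X.shape[1]}"
            )
        return (X - self.mean) / self.sd


def fit_standardizer(train: Dataset | np.ndarray) -> Standardizer:
    """Fit per-feature mean/SD (population SD, ddof=0) on training rows."""
    X = train.features if isinstance(train, Dataset) else np.asarray(train, float)
    if X.shape[0] < 2:
        raise TooFewSamplesError("standardizer needs at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return Standardizer(mean, sd)


@dataclass(frozen=True)
class GNRIInputs:
    """Inputs to the GNRI: serum albumin in g/L, body weights in kg."""

    serum_albumin: float  # g/L
    actual_body_weight: float  # kg
    ideal_body_weight: float  # kg

    def __post_init__(self):
        for name in ("serum_albumin", "actual_body_weight", "ideal_body_weight"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")


def gnri(inputs: GNRIInputs) -> float:
    """Geriatric nutritional risk index.

    GNRI = 14.89 * albumin[g/dL] + 41.7 * (actual weight / ideal weight).
    Albumin is supplied in g/L (the usual laboratory unit) and divided by
    10 internally.
    """
    alb_g_dl = inputs.serum_albumin / 10.0
    return 14.89 * alb_g_dl + 41.7 * (
        inputs.actual_body_weight / inputs.ideal_body_weight
    )
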
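"""Synthetic imbalanced clinical cohorts for end-to-end testing.

The study cohort this generator emulates is a 59-patient hemodialysis
table: 29 clinical features (demographics, comorbidities, blood chemistry,
mineral-bone markers, the GNRI nutrition score) and a 7-level ordinal
vascular-calcification risk label with a heavily imbalanced count profile
(10, 15, 17, 6, 6, 4, 1 patients at levels 0-6).  Only marginal moments
and per-feature Pearson correlations with the risk level are published, so
the generator targets exactly those: each continuous feature is

    mean_j + SD_j * (rho_j * z_level + sqrt(1 - rho_j^2) * eps),

where z_level is the sample's risk level standardized over the cohort's
level distribution and eps is standard normal — a single shared latent
variable rather than a full copula, since the joint is unidentifiable from
the published marginals.  Binary features get level-shifted log-odds whose
slope matches the target point-biserial correlation to first order.
A configurable fraction of majority-class rows is displaced by several SDs
in a random direction to plant outliers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import Dataset
from .errors import CorrelationInfeasibleError, InvalidParameterError

__all__ = [
    "FeatureSpec",
    "CohortSpec",
    "TABLE1_FEATURES",
    "default_cohort_spec",
    "generate_cohort",
    "generate_blobs",
    "plant_label_noise",
    "plant_noise_samples",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One feature's marginal: mean/SD for continuous, prevalence (stored in
    ``mean``) for binary; ``rho`` is the target correlation with the risk
    level."""

    name: str
    mean: float
    sd: float
    rho: float
    binary: bool = False


# 29-feature schema of the emulated cohort: (name, mean-or-prevalence, SD, r).
# Binary prevalences are the "yes" (or male) fraction of 59 patients.
TABLE1_FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec("gender", 32 / 59, 0.0, -0.0455, binary=True),
    FeatureSpec("age", 55.83, 15.60, 0.4010),
    FeatureSpec("smoking", 1 / 59, 0.0, -0.0847, binary=True),
    FeatureSpec("bmi", 23.56, 3.12, 0.1639),
    FeatureSpec("dm", 24 / 59, 0.0, 0.4847, binary=True),
    FeatureSpec("ci", 3 / 59, 0.0, 0.0025, binary=True),
    FeatureSpec("chd", 5 / 59, 0.0, 0.0433, binary=True),
    FeatureSpec("sbp", 155.69, 23.63, -0.1150),
    FeatureSpec("dbp", 88.11, 13.71, -0.2043),
    FeatureSpec("phosphate_binder", 36 / 59, 0.0, -0.2141, binary=True),
    FeatureSpec("hemoglobin", 85.38, 18.12, -0.2584),
    FeatureSpec("crp", 11.74, 35.61, 0.3016),
    FeatureSpec("serum_creatinine", 785.09, 368.62, -0.4252),
    FeatureSpec("serum_glucose", 5.48, 2.28, 0.2608),
    FeatureSpec("serum_calcium", 2.08, 0.24, 0.0520),
    FeatureSpec("serum_phosphorus", 1.81, 0.38, -0.0862),
    FeatureSpec("total_glyceride", 1.69, 1.08, -0.0542),
    FeatureSpec("total_cholesterol", 4.53, 1.42, -0.0466),
    FeatureSpec("ldl_c", 2.45, 0.96, -0.0252),
    FeatureSpec("hdl_c", 0.97, 0.55, 0.0866),
    FeatureSpec("hba1c", 5.82, 1.03, 0.2151),
    FeatureSpec("serum_albumin", 34.31, 6.61, -0.1308),
    FeatureSpec("vitamin_d3", 7.86, 4.55, 0.3850),
    FeatureSpec("ipth", 274.50, 306.31, -0.0225),
    FeatureSpec("gnri", 96.06, 12.76, -0.0078),
    FeatureSpec("fgf23", 32.21, 53.02, -0.0966),
    FeatureSpec("klotho", 2.38, 2.33, 0.0443),
    FeatureSpec("il6", 25.37, 53.69, 0.2634),
    FeatureSpec("fetuin_a", 3.0320e5, 2.0606e5, -0.0234),
)

#: level 0-6 patient counts of the emulated cohort (N = 59)
DEFAULT_LEVEL_COUNTS = (10, 15, 17, 6, 6, 4, 1)


@dataclass(frozen=True)
class CohortSpec:
    n_per_level: tuple = DEFAULT_LEVEL_COUNTS
    features: tuple = TABLE1_FEATURES
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0  # in per-feature SDs
    seed: int = 0

    def __post_init__(self):
        if any(n < 0 for n in self.n_per_level):
            raise InvalidParameterError("level counts must be non-negative")
        if sum(self.n_per_level) < 2:
            raise InvalidParameterError("cohort needs at least 2 samples")
        if not (0.0 <= self.outlier_rate <= 0.5):
            raise InvalidParameterError("outlier_rate must lie in [0, 0.5]")
        if any(f.sd < 0 for f in self.features):
            raise InvalidParameterError("feature SDs must be non-negative")
        if any(abs(f.rho) >= 1 for f in self.features):
            raise InvalidParameterError("|target correlation| must be < 1")


def default_cohort_spec(seed: int = 0, outlier_rate: float = 0.0) -> CohortSpec:
    """The emulated study cohort: 59 samples, 29 features, levels 0-6."""
    return CohortSpec(seed=seed, outlier_rate=outlier_rate)


def _binary_slope(rho: float, p: float) -> float:
    # first-order match of the point-biserial correlation for a logistic
    # level shift: d/dz sigma(logit(p) + beta z) at 0 is beta*p*(1-p), and
    # corr ~ beta * p(1-p) / sqrt(p(1-p)) = beta * sqrt(p(1-p)).
    denom = np.sqrt(p * (1.0 - p))
    if denom < 1e-12:
        if abs(rho) > 1e-12:
            raise CorrelationInfeasibleError(
                f"nonzero correlation {rho} infeasible at prevalence {p}"
            )
        return 0.0
    beta = rho / denom
    if abs(beta) > 20.0:
        raise CorrelationInfeasibleError(
            f"correlation {rho} infeasible at prevalence {p:.3f} (saturated odds)"
        )
    return beta


def generate_cohort(spec: CohortSpec) -> Dataset:
    """Draw a cohort under ``spec``; deterministic given ``spec.seed``.

    Labels are the risk levels 0-6.  Outliers displace a seeded random
    subset of rows of the most populous level by ``outlier_magnitude`` SDs
    along a random unit direction over the continuous features.
    """
    rng = np.random.default_rng(spec.seed)
    levels = np.repeat(
        np.arange(len(spec.n_per_level)), spec.n_per_level
    ).astype(int)
    N, d = levels.size, len(spec.features)

    # standardized level over the cohort's own count profile
    mu_l, sd_l = levels.mean(), levels.std()
    z = (levels - mu_l) / sd_l if sd_l > 0 else np.zeros(N)

    X = np.empty((N, d))
    for j, f in enumerate(spec.features):
        if f.binary:
            p = min(max(f.mean, 1e-9), 1 - 1e-9)
            beta = _binary_slope(f.rho, p)
            logit = np.log(p / (1 - p)) + beta * z
            prob = 1.0 / (1.0 + np.exp(-logit))
            X[:, j] = (rng.random(N) < prob).astype(float)
        else:
            eps = rng.standard_normal(N)
            X[:, j] = f.mean + f.sd * (
                f.rho * z + np.sqrt(1.0 - f.rho**2) * eps
            )

    if spec.outlier_rate > 0:
        major = int(np.argmax(spec.n_per_level))
        rows = np.flatnonzero(levels == major)
        n_out = int(np.floor(spec.outlier_rate * rows.size))
        if n_out > 0:
            chosen = rng.choice(rows, size=n_out, replace=False)
            cont = np.array([not f.binary for f in spec.features])
            sds = np.array([f.sd for f in spec.features])
            for i in chosen:
                direction = rng.standard_normal(int(cont.sum()))
                direction /= np.linalg.norm(direction)
                X[i, cont] += spec.outlier_magnitude * sds[cont] * direction

    names = tuple(f.name for f in spec.features)
    return Dataset(X, levels, names)


def generate_blobs(n_per_class, centers, sd: float, seed: int = 0) -> Dataset:
    """Isotropic Gaussian classes at given centers; class labels 1..c."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n_per_class = tuple(int(n) for n in n_per_class)
    if len(n_per_class) < 2:
        raise InvalidParameterError("need at least 2 classes")
    if centers.shape[0] != len(n_per_class):
        raise InvalidParameterError("one center per class required")
    if sd < 0:
        raise InvalidParameterError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for c, n in enumerate(n_per_class, start=1):
        rows.append(centers[c - 1] + sd * rng.standard_normal((n, centers.shape[1])))
        labels.extend([c] * n)
    X = np.vstack(rows)
    names = tuple(f"x{j}" for j in range(centers.shape[1]))
    return Dataset(X, np.array(labels), names)


def plant_label_noise(
    dataset: Dataset, fraction: float, target_class: int, seed: int = 0
):
    """Flip labels of floor(fraction * class size) seeded-random rows of
    ``target_class`` to a different class; returns (dataset, flipped_idx).

    With two classes the flip goes to the other class; with more, to a
    seeded-random other class per row.
    """
    if not (0.0 <= fraction < 0.5):
        raise InvalidParameterError("fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    y = dataset.labels.copy()
    rows = np.flatnonzero(y == target_class)
    n_flip = int(np.floor(fraction * rows.size))
    flipped = np.sort(rng.choice(rows, size=n_flip, replace=False)) if n_flip else \
        np.empty(0, dtype=int)
    classes = np.unique(dataset.labels)
    others = classes[classes != target_class]
    for i in flipped:
        y[i] = others[0] if others.size == 1 else rng.choice(others)
    return dataset.with_labels(y), flipped


def plant_noise_samples(
    dataset: Dataset,
    fraction: float,
    target_class: int,
    location,
    spread: float,
    seed: int = 0,
):
    """Turn floor(fraction * class size) seeded rows of ``target_class`` into
    noise samples: their features are redrawn as N(location, spread^2 I)
    while their label stays ``target_class``.

    This emulates the mislabeled / corrupted records that accumulate in an
    imbalanced majority class — points whose label disagrees with where
    their features sit.  (A label flip alone cannot model them here: the
    membership function is computed from features only, so relabeling a
    feature-typical row leaves its weight unchanged.)  Returns
    ``(noisy_dataset, noise_row_indices)``.
    """
    if not (0.0 <= fraction < 0.5):
        raise InvalidParameterError("fraction must lie in [0, 0.5)")
    location = np.asarray(location, dtype=float)
    if location.shape != (dataset.d,):
        raise InvalidParameterError("location must have one entry per feature")
    if spread < 0:
        raise InvalidParameterError("spread must be non-negative")
    rng = np.random.default_rng(seed)
    rows = np.flatnonzero(dataset.labels == target_class)
    n = int(np.floor(fraction * rows.size))
    chosen = np.sort(rng.choice(rows, size=n, replace=False)) if n else \
        np.empty(0, dtype=int)
    X = dataset.features.copy()
    for i in chosen:
        X[i] = location + spread * rng.standard_normal(dataset.d)
    return Dataset(X, dataset.labels, dataset.feature_names), chosen
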
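"""Membership weights from Laplacian-regularized self-representation.

Each training sample x_i is expressed as a linear combination of all
training samples, X ≈ XZ, with the coefficient matrix Z smoothed across
similar samples by a normalized-graph-Laplacian penalty:

    min_Z  ||XZ - X||_F^2  +  lambda * Tr(Z L Z^T)

Stationarity gives the Sylvester equation  (X^T X) Z + lambda Z L = X^T X,
solved by Bartels–Stewart.  The per-sample squared reconstruction error
r_i = ||X z_i - x_i||^2 quantifies how inconsistent a sample is with the
cohort's overall linear structure; a min–max map turns r into membership
weights s_i in [0, 1] (best-reconstructed sample -> 1, worst -> 0) that the
fuzzy SVM uses to down-weight outliers.

X is column-per-sample (d x N) throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_sylvester

from .data_model import Dataset, fit_standardizer
from .errors import (
    DimensionMismatchError,
    InvalidParameterError,
    SylvesterSolveError,
    TooFewSamplesError,
    ZeroDegreeError,
)
from .kernels import rbf_kernel

__all__ = [
    "LaplacianBundle",
    "SelfRepResult",
    "build_laplacian",
    "solve_self_representation",
    "reconstruction_errors",
    "membership_from_errors",
    "compute_memberships",
]

#: Laplacian regularization strength; see docs for the default's provenance.
DEFAULT_LAMBDA = 0.01

#: relative ridge added to X^T X; guarantees a unique Sylvester solution
#: when N > d (X^T X rank-deficient, the normal case for tabular cohorts).
DEFAULT_RIDGE_REL = 1e-8


@dataclass(frozen=True)
class LaplacianBundle:
    """Similarity matrix W with its degree matrix, combinatorial Laplacian
    Delta = D - W, and symmetric normalized Laplacian L = D^-1/2 Delta D^-1/2."""

    W: np.ndarray
    degrees: np.ndarray
    Delta: np.ndarray
    L: np.ndarray


@dataclass(frozen=True)
class SelfRepResult:
    Z: np.ndarray
    errors: np.ndarray
    memberships: np.ndarray
    lam: float
    residual: float


def build_laplacian(W: np.ndarray) -> LaplacianBundle:
    """Build the normalized Laplacian bundle from a similarity matrix.

    W must be square, symmetric (within 1e-8) and non-negative; a vertex
    with zero degree makes D^-1/2 undefined and raises ZeroDegreeError.
    L is symmetrized by averaging with its transpose.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise DimensionMismatchError("W must be square")
    if not np.allclose(W, W.T, atol=1e-8):
        raise InvalidParameterError("W must be symmetric")
    if np.any(W < -1e-12):
        raise InvalidParameterError("W must be non-negative")
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        idx = int(np.argmax(deg <= 0))
        raise ZeroDegreeError(f"vertex {idx} has zero degree; Laplacian undefined")
    Delta = np.diag(deg) - W
    dinv = 1.0 / np.sqrt(deg)
    L = Delta * np.outer(dinv, dinv)
    L = 0.5 * (L + L.T)
    return LaplacianBundle(W=W, degrees=deg, Delta=Delta, L=L)


def solve_self_representation(
    X: np.ndarray,
    L: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    ridge: float | None = None,
) -> np.ndarray:
    """Solve (X^T X + ridge I) Z + lam * Z L = X^T X for Z.

    X is d x N (column-per-sample).  With ridge > 0 the left coefficient is
    positive definite and lam*L is PSD, so the two spectra cannot collide
    and the solution is unique.  ``ridge=None`` uses the relative default
    1e-8 * trace(X^T X)/N; pass 0 explicitly to disable it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DimensionMismatchError("X must be a d x N matrix")
    N = X.shape[1]
    L = np.asarray(L, dtype=float)
    if L.shape != (N, N):
        raise DimensionMismatchError(f"L must be {N}x{N}, got {L.shape}")
    if lam < 0:
        raise InvalidParameterError("lambda must be non-negative")
    G = X.T @ X
    if ridge is None:
        ridge = DEFAULT_RIDGE_REL * max(np.trace(G) / N, 1.0)
    A = G + ridge * np.eye(N)
    if lam == 0.0:
        try:
            Z = np.linalg.solve(A, G)
        except np.linalg.LinAlgError as exc:
            raise SylvesterSolveError(
                f"X^T X singular with ridge={ridge}; increase ridge"
            ) from exc
    else:
        try:
            Z = solve_sylvester(A, lam * L, G)
        except Exception as exc:  # scipy raises ValueError on spectrum collision
            raise SylvesterSolveError(
                f"Sylvester solve failed (ridge={ridge}): {exc}; try ridge > 0"
            ) from exc
    resid = np.linalg.norm(A @ Z + lam * Z @ L - G, "fro")
    if not np.isfinite(resid) or resid > 1e-6 * (1.0 + np.linalg.norm(G, "fro")):
        raise SylvesterSolveError(
            f"Sylvester residual {resid:.3e} above tolerance; try larger ridge"
        )
    return Z


def reconstruction_errors(X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """r_i = ||X z_i - x_i||^2 for each column i."""
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if X.ndim != 2 or Z.shape != (X.shape[1], X.shape[1]):
        raise DimensionMismatchError(
            f"X is {X.shape}, Z must be {X.shape[1]}x{X.shape[1]}, got {Z.shape}"
        )
    R = X @ Z - X
    return np.sum(R * R, axis=0)


def membership_from_errors(r: np.ndarray, floor: float = 0.0) -> np.ndarray:
    """Affine min–max map: s_i = 1 - (r_i - r_min)/(r_max - r_min).

    If all errors coincide (within 1e-12 relative) every sample gets full
    membership 1.  ``floor`` clips s from below so the worst sample is
    never excluded entirely (default 0, the literal map).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidParameterError("reconstruction errors must be non-negative")
    rmin, rmax = float(r.min()), float(r.max())
    if rmax - rmin <= 1e-12 * max(rmax, 1.0):
        return np.ones_like(r)
    s = 1.0 - (r - rmin) / (rmax - rmin)
    return np.clip(s, floor, 1.0)


def compute_memberships(
    train: Dataset | np.ndarray,
    gamma_sim: float,
    lam: float = DEFAULT_LAMBDA,
    ridge: float | None = None,
    standardize: bool = True,
    membership_floor: float = 0.0,
    exclude_self: bool = True,
) -> SelfRepResult:
    """Full membership pipeline on a training set.

    Standardize -> W = RBF Gram -> normalized Laplacian -> Sylvester solve
    -> reconstruction errors -> min-max memberships.  W keeps its unit
    diagonal (self-similarity), which guarantees positive degrees.

    ``exclude_self`` (default True) zeroes the diagonal of Z before the
    error computation, so r_i measures how well sample i is represented by
    the *other* training samples.  This matters: the unconstrained solution
    lets every sample lean on its own column (z_i ~ e_i reconstructs x_i
    exactly no matter how atypical it is), which would hand outliers the
    *lowest* errors — the smoothing penalty vanishes on samples similar to
    nobody.  Discounting the self-coefficient restores the intended
    reading: a sample far from the cohort's structure cannot be rebuilt
    from its peers and gets a large error, hence a small membership.
    """
    Xrows = train.features if isinstance(train, Dataset) else np.asarray(train, float)
    if Xrows.shape[0] < 3:
        raise TooFewSamplesError("self-representation needs N >= 3 samples")
    if standardize:
        Xrows = fit_standardizer(Xrows).transform(Xrows)
    W = rbf_kernel(Xrows, Xrows, gamma_sim)
    bundle = build_laplacian(W)
    X = Xrows.T  # d x N
    Z = solve_self_representation(X, bundle.L, lam=lam, ridge=ridge)
    Z_err = Z - np.diag(np.diag(Z)) if exclude_self else Z
    r = reconstruction_errors(X, Z_err)
    s = membership_from_errors(r, floor=membership_floor)
    G = X.T @ X
    ridge_eff = (
        DEFAULT_RIDGE_REL * max(np.trace(G) / X.shape[1], 1.0)
        if ridge is None
        else ridge
    )
    resid = np.linalg.norm(
        (G + ridge_eff * np.eye(G.shape[0])) @ Z + lam * Z @ bundle.L - G, "fro"
    )
    return SelfRepResult(Z=Z, errors=r, memberships=s, lam=lam, residual=resid)
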
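"""Fuzzy SVM: weighted-box dual solver, decision function, one-vs-one multiclass.

The binary dual is the standard C-SVM quadratic program with the box upper
bound individualized per sample by its membership weight:

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   0 <= a_i <= s_i * C,   sum_i a_i y_i = 0.

A sample with membership s_i = 0 is forced to a_i = 0 and cannot become a
support vector, which is how outliers are suppressed.  Because stock
unweighted solvers assume a common box, the dual is solved here by an
SMO-style maximal-violating-pair algorithm with per-sample bounds
(LIBSVM's working-set selection generalized to the box 0..s_i*C).

Multiclass uses one-against-one: one binary machine per unordered class
pair, majority vote, deterministic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data_model import Dataset
from .errors import (
    ConvergenceError,
    DimensionMismatchError,
    EmptyClassError,
    InvalidParameterError,
    SingleClassError,
)
from .kernels import rbf_kernel

__all__ = [
    "FSVMHyperParams",
    "BinaryFSVMModel",
    "MultiClassModel",
    "smo_solve",
    "fit_binary",
    "decision_value",
    "fit_multiclass",
    "predict",
]


@dataclass(frozen=True)
class FSVMHyperParams:
    """C: slack penalty; gamma: RBF bandwidth; tol: KKT stopping tolerance."""

    C: float = 1.0
    gamma: float = 1.0
    tol: float = 1e-6
    max_iter: int = 100_000

    def __post_init__(self):
        if self.C <= 0:
            raise InvalidParameterError(f"C must be > 0, got {self.C}")
        if self.gamma <= 0:
            raise InvalidParameterError(f"gamma must be > 0, got {self.gamma}")
        if self.tol <= 0:
            raise InvalidParameterError("tol must be > 0")


def smo_solve(K, y, upper, tol=1e-6, max_iter=100_000):
    """Minimize 1/2 a'Qa - 1'a with Q_ij = y_i y_j K_ij, subject to
    y'a = 0 and 0 <= a_i <= upper_i.

    Maximal-violating-pair working-set selection; returns (alpha, bias).
    The bias is the mean over free vectors of y_i - f0(x_i), falling back
    to the midpoint of the KKT-implied interval when no vector is free.
    """
    K = np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    upper = np.asarray(upper, dtype=float)
    N = y.shape[0]
    alpha = np.zeros(N)
    # gradient of the dual objective: G_i = sum_j Q_ij a_j - 1
    G = -np.ones(N)
    yG = -y * G  # the violating-pair criterion value

    for it in range(max_iter):
        up_mask = ((y > 0) & (alpha < upper - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low_mask = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < upper - 1e-12))
        if not up_mask.any() or not low_mask.any():
            break
        yG = -y * G
        i = int(np.flatnonzero(up_mask)[np.argmax(yG[up_mask])])
        j = int(np.flatnonzero(low_mask)[np.argmin(yG[low_mask])])
        if yG[i] - yG[j] < tol:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        eta = max(eta, 1e-12)
        # step t along the feasible direction a_i += y_i t, a_j -= y_j t
        t = (yG[i] - yG[j]) / eta
        # box clipping
        if y[i] > 0:
            t = min(t, upper[i] - alpha[i])
        else:
            t = min(t, alpha[i])
        if y[j] > 0:
            t = min(t, alpha[j])
        else:
            t = min(t, upper[j] - alpha[j])
        if t <= 0:
            break
        alpha[i] += y[i] * t
        alpha[j] -= y[j] * t
        np.clip(alpha, 0.0, upper, out=alpha)
        G += t * y * (K[:, i] - K[:, j])
    else:
        raise ConvergenceError(f"SMO did not converge within {max_iter} iterations")

    # bias from KKT: f0_i = sum_j a_j y_j K_ij;  G_i = y_i f0_i - 1
    f0 = y * (G + 1.0)
    free = (alpha > tol) & (alpha < upper - tol)
    if free.any():
        b = float(np.mean(y[free] - f0[free]))
    else:
        # bounds from non-free samples: a_i = 0 -> y_i(f0_i+b) >= 1, etc.
        yG = -y * G
        up_mask = ((y > 0) & (alpha < upper - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low_mask = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < upper - 1e-12))
        hi = yG[up_mask].max() if up_mask.any() else 0.0
        lo = yG[low_mask].min() if low_mask.any() else 0.0
        b = float((hi + lo) / 2.0)
    return alpha, b


@dataclass(frozen=True)
class BinaryFSVMModel:
    alphas: np.ndarray
    bias: float
    support_idx: np.ndarray
    train_X: np.ndarray
    train_y: np.ndarray  # in {-1, +1}
    memberships: np.ndarray
    params: FSVMHyperParams


def fit_binary(
    X: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    params: FSVMHyperParams,
    K: np.ndarray | None = None,
) -> BinaryFSVMModel:
    """Fit the weighted-box dual on labels y in {-1,+1} with memberships s.

    The Gram matrix is computed from X with the RBF bandwidth in ``params``
    unless a precomputed K is passed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise InvalidParameterError("binary labels must be in {-1, +1}")
    if np.any((s < 0) | (s > 1)):
        raise InvalidParameterError("memberships must lie in [0, 1]")
    eff = s > 0
    if len(set(y[eff])) < 2:
        raise SingleClassError(
            "only one effective class among samples with positive membership"
        )
    if K is None:
        K = rbf_kernel(X, X, params.gamma)
    upper = s * params.C
    alpha, b = smo_solve(K, y, upper, tol=params.tol, max_iter=params.max_iter)
    support = np.flatnonzero(alpha > params.tol)
    return BinaryFSVMModel(
        alphas=alpha,
        bias=b,
        support_idx=support,
        train_X=X,
        train_y=y.astype(int),
        memberships=s,
        params=params,
    )


def decision_value(model: BinaryFSVMModel, x: np.ndarray) -> np.ndarray:
    """f(x) = sum_i y_i a_i K(x, x_i) + b; the predicted label is its sign
    (sign(0) -> +1).  Accepts a single row or a matrix of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.train_X.shape[1]:
        raise DimensionMismatchError(
            f"model expects d={model.train_X.shape[1]}, got {X.shape[1]}"
        )
    Kx = rbf_kernel(X, model.train_X, model.params.gamma)
    vals = Kx @ (model.alphas * model.train_y) + model.bias
    return float(vals[0]) if single else vals


@dataclass(frozen=True)
class MultiClassModel:
    """One-against-one ensemble: machines[(p, q)] scores +1 for class p."""

    class_labels: tuple[int, ...]
    machines: dict[tuple[int, int], BinaryFSVMModel]
    params: FSVMHyperParams


def fit_multiclass(
    train: Dataset,
    s: np.ndarray,
    params: FSVMHyperParams,
) -> MultiClassModel:
    """Fit c(c-1)/2 pairwise machines on an already-standardized Dataset.

    Memberships are computed once on the full training fold and sliced per
    pair (never recomputed on the pair subset).  Orientation: in each pair
    (p, q) with p < q, class p is the +1 side.
    """
    y = train.labels
    classes = tuple(int(c) for c in np.unique(y))
    if len(classes) < 2:
        raise SingleClassError("multiclass fit needs at least 2 classes")
    s = np.asarray(s, dtype=float)
    if s.shape != (train.N,):
        raise DimensionMismatchError("membership vector length must equal N")
    machines = {}
    for p, q in combinations(classes, 2):
        mask = (y == p) | (y == q)
        if not np.any(y == p) or not np.any(y == q):
            raise EmptyClassError(f"class pair ({p},{q}) has an empty side")
        yy = np.where(y[mask] == p, 1.0, -1.0)
        machines[(p, q)] = fit_binary(train.features[mask], yy, s[mask], params)
    return MultiClassModel(class_labels=classes, machines=machines, params=params)


def predict(model: MultiClassModel, X: np.ndarray):
    """Majority vote over pairwise winners.

    Returns ``(labels, scores)`` where ``scores`` is the raw decision value
    of the single machine when c = 2 (for ROC), else None.  Ties are broken
    by the largest sum of pairwise decision-value magnitudes in the tied
    class's favor, then by the smaller class index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    classes = model.class_labels
    if n == 0:
        empty = np.empty(0, dtype=int)
        return (empty, np.empty(0)) if len(classes) == 2 else (empty, None)
    votes = np.zeros((n, len(classes)))
    margin = np.zeros((n, len(classes)))
    cidx = {c: k for k, c in enumerate(classes)}
    for (p, q), machine in model.machines.items():
        vals = decision_value(machine, X)
        win_p = vals >= 0  # sign(0) -> +1 convention
        votes[win_p, cidx[p]] += 1
        votes[~win_p, cidx[q]] += 1
        margin[win_p, cidx[p]] += np.abs(vals[win_p])
        margin[~win_p, cidx[q]] += np.abs(vals[~win_p])
    labels = np.empty(n, dtype=int)
    for i in range(n):
        best = votes[i].max()
        tied = np.flatnonzero(votes[i] == best)
        if len(tied) > 1:
            tied = tied[margin[i, tied] == margin[i, tied].max()]
        labels[i] = classes[tied.min()]
    if len(classes) == 2:
        (p, q) = next(iter(model.machines))
        return labels, decision_value(model.machines[(p, q)], X)
    return labels, None
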
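"""RBF (Gaussian) kernel construction.

The same kernel serves two roles: the Gram matrix of the classifier and the
sample-similarity matrix W feeding the graph Laplacian of the
self-representation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionMismatchError, InvalidParameterError

__all__ = ["KernelMatrix", "rbf_kernel"]


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric RBF Gram matrix with its bandwidth.

    Entries lie in (0, 1] with unit diagonal; PSD by Bochner's theorem.
    """

    values: np.ndarray
    gamma: float


def rbf_kernel(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """K(a_i, b_j) = exp(-gamma * ||a_i - b_j||^2), computed via the
    ||a||^2 + ||b||^2 - 2 a.b expansion with tiny negatives clamped to 0."""
    if gamma <= 0:
        raise InvalidParameterError(f"gamma must be > 0, got {gamma}")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise DimensionMismatchError(
            f"feature dimensions differ: {A.shape[1]} vs {B.shape[1]}"
        )
    sq = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    np.clip(sq, 0.0, None, out=sq)
    K = np.exp(-gamma * sq)
    if A is B or (A.shape == B.shape and np.array_equal(A, B)):
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
    return K


def rbf_gram(X: np.ndarray, gamma: float) -> KernelMatrix:
    """Convenience wrapper returning a :class:`KernelMatrix` for K(X, X)."""
    return KernelMatrix(rbf_kernel(X, X, gamma), gamma)
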
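"""Heartbeat signal smoothing and PCA decomposition.

The heartbeat record is a 2-D matrix X(i, j) with N fast-time rows (e.g.
one per sensor site) and M slow-time columns (successive observations).
The processing chain is: slow-time moving-average smoothing, per-row mean
centring, eigendecomposition of the fast-time covariance, and projection
onto the leading principal components.

Conventions chosen where the procedure leaves them open: smoothing windows
are truncated at the sequence boundary and renormalised by the actual
window length (no phantom zeros); the covariance uses the sample divisor
M - 1, which makes eigenvalues and singular values satisfy
lambda = s^2 / (M - 1); eigenvector signs are fixed by forcing the
largest-magnitude component non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PreconditionError

__all__ = [
    "DEFAULT_SMOOTH_R",
    "PCADecomposition",
    "smooth_slow_time",
    "mean_center",
    "pca_decompose",
    "pca_project",
]

#: Default smoothing half-window: a 5-sample window, mirroring the 5x5
#: spatial smoothing unit used on images.
DEFAULT_SMOOTH_R = 2


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D signal matrix, got {X.ndim}-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("signal matrix contains non-finite values")
    return X


def smooth_slow_time(X, R: int = DEFAULT_SMOOTH_R) -> np.ndarray:
    """Moving average over the slow-time window j-R ... j+R, per row.

    All entries are updated simultaneously from the original matrix.
    Windows are truncated at the edges and renormalised, so R = 0 is the
    identity and a constant matrix is a fixed point for any R.
    """
    X = _as_matrix(X)
    if not float(R).is_integer() or R < 0:
        raise ValueError("R must be a non-negative integer")
    R = int(R)
    if R == 0:
        return X.copy()
    n, m = X.shape
    cs = np.zeros((n, m + 1))
    np.cumsum(X, axis=1, out=cs[:, 1:])
    j = np.arange(m)
    lo = np.clip(j - R, 0, m)
    hi = np.clip(j + R + 1, 0, m)
    return (cs[:, hi] - cs[:, lo]) / (hi - lo)


def mean_center(X) -> np.ndarray:
    """Subtract each row's slow-time mean; every output row sums to 0."""
    X = _as_matrix(X)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 slow-time observations to centre")
    return X - X.mean(axis=1, keepdims=True)


@dataclass(frozen=True)
class PCADecomposition:
    """Eigen- and singular-value decomposition of the fast-time covariance.

    ``eigenvalues`` are sorted non-increasing and satisfy
    sum(eigenvalues) = trace of the covariance; ``singular_values`` come
    from the SVD of the centred matrix and satisfy
    eigenvalues[k] = singular_values[k]^2 / (M - 1) on the shared rank.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray       # orthonormal columns (N x N)
    singular_values: np.ndarray
    right_vectors: np.ndarray      # orthonormal columns (M x r)


def _fix_signs(V: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component of each column non-negative."""
    V = V.copy()
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return V


def pca_decompose(Xc) -> PCADecomposition:
    """Eigendecomposition of C = Xc Xc^T / (M - 1) for a centred matrix."""
    Xc = _as_matrix(Xc)
    n, m = Xc.shape
    if m < 2:
        raise ValueError("need at least 2 slow-time observations")
    tol = 1e-8 * max(1.0, float(np.abs(Xc).max()))
    if np.abs(Xc.mean(axis=1)).max() > tol:
        raise PreconditionError("input rows are not mean-centred; call mean_center first")
    C = Xc @ Xc.T / (m - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], _fix_signs(evecs[:, order])
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return PCADecomposition(
        eigenvalues=evals,
        eigenvectors=evecs,
        singular_values=s,
        right_vectors=_fix_signs(Vt.T),
    )


def pca_project(Xc, dec: PCADecomposition, k: int) -> np.ndarray:
    """Project the centred matrix onto the k leading components: Yk = Uk^T Xc."""
    Xc = _as_matrix(Xc)
    n = dec.eigenvectors.shape[1]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    return dec.eigenvectors[:, :k].T @ Xc
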
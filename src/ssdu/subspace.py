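"""PCA over the 5D reduced conformational coordinates.

Low-energy docking clusters are anisotropic: the energy rises steeply along
two or so "restrictive" directions and varies smoothly along the remaining
"permissive" ones, and the permissive directions carry most of the sample
variance.  Fitting a PCA basis to a cluster therefore splits the 5D reduced
space into a (default 3D) permissive subspace -- where underestimation
happens -- and its restrictive complement.

sigma_i are standard deviations (square roots of covariance eigenvalues,
the SVD singular-value convention); explained-variance fractions use their
squares.  Covariance is normalized by 1/(K-1).  Each basis column's sign is
fixed so its largest-magnitude entry is positive, making the transform
reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCABasis", "fit_pca", "to_principal", "from_principal", "permissive", "explained_fraction"]


@dataclass(frozen=True)
class PCABasis:
    """Orthogonal basis W (columns = principal directions, variance-ordered),
    per-direction standard deviations sigma (descending) and sample mean xbar.

    Principal coordinates: ``z = W.T @ (x - xbar)``; inverse ``x = W @ z + xbar``.
    """

    W: np.ndarray
    sigma: np.ndarray
    xbar: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        xbar = np.asarray(self.xbar, dtype=float)
        n = xbar.shape[0]
        if W.shape != (n, n) or sigma.shape != (n,):
            raise ValueError("inconsistent basis shapes")
        if not np.allclose(W.T @ W, np.eye(n), atol=1e-10):
            raise ValueError("W must be orthogonal within 1e-10")
        if np.any(sigma < -1e-15) or np.any(np.diff(sigma) > 1e-12):
            raise ValueError("sigma must be non-negative and sorted descending")
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "sigma", np.maximum(sigma, 0.0))
        object.__setattr__(self, "xbar", xbar)

    @property
    def dim(self) -> int:
        return self.xbar.shape[0]


def fit_pca(X: np.ndarray, standardize: bool = False) -> PCABasis:
    """Fit a PCA basis to K >= 2 samples (rows of X).

    Eigendecomposition of the 1/(K-1)-normalized sample covariance;
    zero-variance directions are allowed (sigma_i = 0).  With
    ``standardize`` the coordinates are z-scored first (off by default: the
    five reduced coordinates share angular units).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K, n = X.shape
    if K < 2:
        raise ValueError(f"PCA requires at least 2 samples, got {K}")
    xbar = X.mean(axis=0)
    Xc = X - xbar
    if standardize:
        s = Xc.std(axis=0, ddof=1)
        s[s == 0] = 1.0
        Xc = Xc / s
    cov = (Xc.T @ Xc) / (K - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    W = evecs[:, order]
    # deterministic sign: largest-|entry| of each column is positive
    for j in range(n):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return PCABasis(W=W, sigma=np.sqrt(evals), xbar=xbar)


def to_principal(basis: PCABasis, x: np.ndarray) -> np.ndarray:
    """Map x (sample or (K, n) stack) to principal coordinates z = W'(x - xbar)."""
    x = np.asarray(x, dtype=float)
    return (x - basis.xbar) @ basis.W


def from_principal(basis: PCABasis, z: np.ndarray) -> np.ndarray:
    """Inverse transform x = W z + xbar."""
    z = np.asarray(z, dtype=float)
    return z @ basis.W.T + basis.xbar


def permissive(z: np.ndarray, n_permissive: int = 3) -> np.ndarray:
    """First ``n_permissive`` principal coordinates (the permissive subspace)."""
    z = np.asarray(z, dtype=float)
    if not 1 <= n_permissive <= z.shape[-1]:
        raise ValueError(f"n_permissive must be in [1, {z.shape[-1]}], got {n_permissive}")
    return z[..., :n_permissive]


def explained_fraction(basis: PCABasis, k: int) -> float:
    """Fraction of total variance carried by the top-k principal directions."""
    if not 1 <= k <= basis.dim:
        raise ValueError(f"k must be in [1, {basis.dim}], got {k}")
    var = basis.sigma**2
    total = var.sum()
    if total == 0:
        raise ValueError("explained fraction undefined for zero-variance data")
    return float(var[:k].sum() / total)
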
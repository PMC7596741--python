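"""Linear canonical correlation analysis between firing rates and kinematics.

Two data views — the (n_bins, m) smoothed square-root firing rates ``Z``
and the (n_bins, 3) kinematics ``X`` = [vx, vy, speed] — are projected
onto paired canonical variables chosen to maximize the Pearson
correlation of each pair, subject to unit variance on the training data.
With 3 kinematic variables and m > 3 units, exactly ``min(m, 3) = 3``
pairs exist.

The fit centers both views, whitens each with a ridge-regularized
covariance inverse square root, and takes the SVD of the whitened
cross-covariance; singular values are the canonical correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LinearCanonicalModel",
    "fit_lcca",
    "transform_lcca",
    "canonical_correlations",
    "total_correlation",
    "invert_cca_velocity",
    "SingularCovarianceError",
]


class SingularCovarianceError(Exception):
    """Covariance is numerically singular; pass a ridge > 0 to regularize."""


@dataclass
class LinearCanonicalModel:
    """Fitted linear CCA between rates (view Z) and kinematics (view X)."""

    alpha: np.ndarray  # (m, k) neural canonical coefficients
    beta: np.ndarray  # (3, k) kinematic canonical coefficients
    rho: np.ndarray  # (k,) training canonical correlations, descending
    mean_z: np.ndarray
    mean_x: np.ndarray
    ridge: float = 0.0
    extras: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.rho)


def _inv_sqrt(S: np.ndarray, ridge: float) -> np.ndarray:
    Sr = S + ridge * np.eye(len(S))
    w, V = np.linalg.eigh(Sr)
    if w.min() <= 1e-14 * max(w.max(), 1.0):
        raise SingularCovarianceError(
            "covariance numerically singular; increase the ridge parameter"
        )
    return (V / np.sqrt(w)) @ V.T


def fit_lcca(Z_train: np.ndarray, X_train: np.ndarray, ridge: float = 1e-8) -> LinearCanonicalModel:
    """Fit linear CCA on training data (whitening + SVD route)."""
    Z = np.asarray(Z_train, float)
    X = np.asarray(X_train, float)
    n, m = Z.shape
    p = X.shape[1]
    if n < m + p:
        raise ValueError(f"need at least m+{p} = {m + p} training bins, got {n}")
    mean_z, mean_x = Z.mean(axis=0), X.mean(axis=0)
    Zc, Xc = Z - mean_z, X - mean_x
    Szz = Zc.T @ Zc / (n - 1)
    Sxx = Xc.T @ Xc / (n - 1)
    Szx = Zc.T @ Xc / (n - 1)
    Wz = _inv_sqrt(Szz, ridge)
    Wx = _inv_sqrt(Sxx, ridge)
    U, s, Vt = np.linalg.svd(Wz @ Szx @ Wx)
    k = min(m, p)
    alpha = Wz @ U[:, :k]
    beta = Wx @ Vt[:k].T
    rho = np.clip(s[:k], 0.0, 1.0)
    return LinearCanonicalModel(
        alpha=alpha, beta=beta, rho=rho, mean_z=mean_z, mean_x=mean_x, ridge=ridge
    )


def transform_lcca(
    model: LinearCanonicalModel, Z: np.ndarray | None = None, X: np.ndarray | None = None
):
    """Project new data onto the canonical variables (training means used).

    Returns (Z_LCV, X_LCV); either entry is None when that view was not
    supplied.
    """
    U = V = None
    if Z is not None:
        Z = np.asarray(Z, float)
        if Z.shape[1] != model.alpha.shape[0]:
            raise ValueError("Z has wrong number of units for this model")
        U = (Z - model.mean_z) @ model.alpha
    if X is not None:
        X = np.asarray(X, float)
        if X.shape[1] != model.beta.shape[0]:
            raise ValueError("X has wrong number of kinematic variables")
        V = (X - model.mean_x) @ model.beta
    return U, V


def canonical_correlations(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pearson correlation of corresponding columns of two matrices."""
    U = np.atleast_2d(np.asarray(U, float))
    V = np.atleast_2d(np.asarray(V, float))
    if U.shape != V.shape:
        raise ValueError("U and V must have identical shapes")
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    num = np.einsum("ij,ij->j", Uc, Vc)
    den = np.sqrt(np.einsum("ij,ij->j", Uc, Uc) * np.einsum("ij,ij->j", Vc, Vc))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    return rho


def total_correlation(U: np.ndarray, V: np.ndarray) -> float:
    """Sum of per-pair correlations (the canonical training objective)."""
    return float(np.sum(canonical_correlations(U, V)))


def invert_cca_velocity(
    Z_CV_test: np.ndarray,
    model,
    Z_CV_train: np.ndarray,
    X_CV_train: np.ndarray,
):
    """Velocity reconstruction through the CCA mapping alone (no decoder).

    Per canonical pair k, a univariate regression X_k = a0 + a1 Z_k is
    fitted on the training canonical variables; the estimated kinematic
    canonical variables are then mapped back to kinematics by inverting
    the kinematic-side mapping.  For the linear model that inversion is
    ``x = mean_x + (beta^T)^+ u_X``.  Deep models route through their own
    layer-by-layer inversion (see dcca.invert_dcca_velocity).

    This is a deliberately simple baseline: it is expected to decode
    worse than a proper state-space decoder on the same representation.
    Returns the (n, 2) velocity estimate.
    """
    from .dcca import DeepCanonicalModel, invert_dcca_velocity

    coef = _fit_pairwise_regression(Z_CV_train, X_CV_train)
    X_CV_hat = coef[0] + Z_CV_test * coef[1]
    if isinstance(model, DeepCanonicalModel):
        return invert_dcca_velocity(X_CV_hat, model)
    X_hat = model.mean_x + X_CV_hat @ np.linalg.pinv(model.beta.T).T
    return X_hat[:, :2]


def _fit_pairwise_regression(Z_CV: np.ndarray, X_CV: np.ndarray) -> np.ndarray:
    """Per-pair univariate OLS X_k = a0 + a1 Z_k; returns (2, k)."""
    Zc = Z_CV - Z_CV.mean(axis=0)
    var = np.einsum("ij,ij->j", Zc, Zc)
    cov = np.einsum("ij,ij->j", Zc, X_CV - X_CV.mean(axis=0))
    a1 = np.where(var > 0, cov / np.maximum(var, 1e-30), 0.0)
    a0 = X_CV.mean(axis=0) - a1 * Z_CV.mean(axis=0)
    return np.vstack([a0, a1])
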
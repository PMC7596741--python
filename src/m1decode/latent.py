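"""Unsupervised latent representations of population firing: PCA, FA, LDS.

These are the kinematics-blind baselines: principal components, factor
scores (shared variability with per-unit uniquenesses), and causally
filtered latent states of a linear dynamical system.  Dimensionality is
selected by test-set reconstruction error, scanning a candidate grid and
taking the argmin of the mean absolute error between true and
reconstructed rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA, FactorAnalysis

__all__ = [
    "LatentModel",
    "fit_pca",
    "fit_fa",
    "fit_lds",
    "estimate_states",
    "reconstruct",
    "select_dimensionality",
    "pca_candidates",
    "fa_lds_candidates",
]


@dataclass
class LatentModel:
    """Fitted latent-variable model of (n_bins, m) firing rates.

    loadings maps latents to observations: z ~ mean + loadings @ s.
    For LDS, ``transition`` and ``state_noise`` define the latent
    dynamics and ``noise_var`` is the diagonal observation noise.
    """

    method: str  # "pca" | "fa" | "lds"
    q: int
    mean: np.ndarray
    loadings: np.ndarray  # (m, q)
    noise_var: np.ndarray | None = None  # (m,) diagonal
    transition: np.ndarray | None = None  # (q, q), LDS only
    state_noise: np.ndarray | None = None  # (q, q), LDS only
    init_state_cov: np.ndarray | None = None  # (q, q), LDS only
    eigvals: np.ndarray | None = None  # PCA spectrum
    loglik_curve: np.ndarray | None = None  # EM trace (FA / LDS)
    converged: bool = True
    extras: dict = field(default_factory=dict)


def fit_pca(Z_train: np.ndarray) -> LatentModel:
    """PCA on single-trial (binned) rates; keeps all rank components."""
    Z_train = np.asarray(Z_train, float)
    n, m = Z_train.shape
    if n < m:
        warnings.warn(
            f"fewer bins ({n}) than units ({m}); keeping rank-limited components",
            RuntimeWarning,
        )
    p = PCA(n_components=min(n, m), svd_solver="full")
    p.fit(Z_train)
    return LatentModel(
        method="pca",
        q=p.n_components_,
        mean=p.mean_,
        loadings=p.components_.T.copy(),
        eigvals=p.explained_variance_.copy(),
    )


def fit_fa(Z_train: np.ndarray, q: int, max_iter: int = 500, tol: float = 1e-3) -> LatentModel:
    """Factor analysis by EM: loadings + diagonal uniquenesses.

    The per-iteration log-likelihood trace is stored; a model that hits
    max_iter without meeting tol is flagged (converged=False), not
    rejected.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    Z_train = np.asarray(Z_train, float)
    fa = FactorAnalysis(n_components=q, max_iter=max_iter, tol=tol, svd_method="lapack")
    fa.fit(Z_train)
    return LatentModel(
        method="fa",
        q=q,
        mean=fa.mean_,
        loadings=fa.components_.T.copy(),
        noise_var=fa.noise_variance_.copy(),
        loglik_curve=np.asarray(fa.loglike_),
        converged=fa.n_iter_ < max_iter,
        extras={"sk_model": fa},
    )


# ---------------------------------------------------------------------------
# Linear dynamical system: s_t = A s_{t-1} + w,  z_t = mean + C s_t + v
# with diagonal observation noise (per-unit uniquenesses), fitted by EM.
# ---------------------------------------------------------------------------


def _kalman_filter(model: LatentModel, Z: np.ndarray, with_loglik: bool = False):
    """Causal Kalman filter. Returns filtered means (T, q) and, for EM,
    predicted/filtered covariances and the log-likelihood."""
    A, C = model.transition, model.loadings
    Q, Rd = model.state_noise, model.noise_var
    q = model.q
    Zc = Z - model.mean
    T = len(Zc)
    Rinv = 1.0 / Rd
    CtRi = C.T * Rinv  # (q, m)
    CtRiC = CtRi @ C

    mu_f = np.zeros((T, q))
    V_f = np.zeros((T, q, q))
    V_p = np.zeros((T, q, q))
    ll = 0.0
    mu_prev = np.zeros(q)
    V_prev = model.init_state_cov
    Iq = np.eye(q)
    for t in range(T):
        if t == 0:
            mu_pred, V_pred = np.zeros(q), model.init_state_cov.copy()
        else:
            mu_pred = A @ mu_prev
            V_pred = A @ V_prev @ A.T + Q
        # posterior via information form (diagonal R -> q x q inverses only)
        Vp_inv = np.linalg.inv(V_pred + 1e-12 * Iq)
        V_post = np.linalg.inv(Vp_inv + CtRiC)
        innov = Zc[t] - C @ mu_pred
        mu_post = mu_pred + V_post @ (CtRi @ innov)
        if with_loglik:
            # log N(z_t; C mu_pred, C V_pred C^T + R) by the determinant lemma
            M = Vp_inv + CtRiC
            sign, logdet_M = np.linalg.slogdet(M)
            _, logdet_Vp = np.linalg.slogdet(V_pred + 1e-12 * Iq)
            logdet_S = logdet_M + logdet_Vp + np.sum(np.log(Rd))
            # quadratic form via Woodbury
            u = Rinv * innov
            quad = innov @ u - (C.T @ u) @ np.linalg.solve(M, C.T @ u)
            ll += -0.5 * (len(Rd) * np.log(2 * np.pi) + logdet_S + quad)
        mu_f[t], V_f[t], V_p[t] = mu_post, V_post, V_pred
        mu_prev, V_prev = mu_post, V_post
    return mu_f, V_f, V_p, ll


def _kalman_smoother(model, Z):
    """RTS smoother + pairwise covariances (EM E-step)."""
    A = model.transition
    mu_f, V_f, V_p, ll = _kalman_filter(model, Z, with_loglik=True)
    T, q = mu_f.shape
    mu_s = mu_f.copy()
    V_s = V_f.copy()
    V_pair = np.zeros((T - 1, q, q))  # Cov(s_{t+1}, s_t | all data)
    for t in range(T - 2, -1, -1):
        J = V_f[t] @ A.T @ np.linalg.inv(V_p[t + 1] + 1e-12 * np.eye(q))
        mu_s[t] = mu_f[t] + J @ (mu_s[t + 1] - A @ mu_f[t])
        V_s[t] = V_f[t] + J @ (V_s[t + 1] - V_p[t + 1]) @ J.T
        V_pair[t] = V_s[t + 1] @ J.T
    return mu_s, V_s, V_pair, ll


def fit_lds(
    Z_train: np.ndarray,
    q: int,
    max_iter: int = 50,
    tol: float = 1e-4,
    seed: int = 0,
) -> LatentModel:
    """EM for a linear-Gaussian state-space model of population rates.

    Initialization is deterministic (FA-style loadings from PCA, A = 0.9 I),
    so repeated fits are identical.  The log-likelihood trace is stored and
    is non-decreasing up to numerical tolerance.  A fitted transition with
    spectral radius > 1.05 triggers a warning (unstable dynamics).
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    Z_train = np.asarray(Z_train, float)
    T, m = Z_train.shape
    mean = Z_train.mean(axis=0)
    Zc = Z_train - mean

    pca = fit_pca(Z_train)
    C = pca.loadings[:, :q] * np.sqrt(np.maximum(pca.eigvals[:q], 1e-6))
    model = LatentModel(
        method="lds",
        q=q,
        mean=mean,
        loadings=C,
        noise_var=np.maximum(Z_train.var(axis=0) * 0.5, 1e-6),
        transition=0.9 * np.eye(q),
        state_noise=np.eye(q) * 0.1,
        init_state_cov=np.eye(q),
    )

    lls = []
    for it in range(max_iter):
        mu, V, V_pair, ll = _kalman_smoother(model, Z_train)
        lls.append(ll)
        if it > 0 and abs(lls[-1] - lls[-2]) < tol * abs(lls[-2]):
            break
        # sufficient statistics
        S = mu.T @ mu + V.sum(axis=0)  # sum E[s s^T]
        S0 = S - (np.outer(mu[-1], mu[-1]) + V[-1])  # t = 1..T-1
        S1 = S - (np.outer(mu[0], mu[0]) + V[0])  # t = 2..T
        Scross = mu[1:].T @ mu[:-1] + V_pair.sum(axis=0)  # E[s_t s_{t-1}^T]
        # M-step
        A = Scross @ np.linalg.inv(S0)
        Qn = (S1 - A @ Scross.T) / (T - 1)
        Qn = (Qn + Qn.T) / 2 + 1e-9 * np.eye(q)
        C = (Zc.T @ mu) @ np.linalg.inv(S)
        R = (np.einsum("ti,ti->i", Zc, Zc) - np.einsum("ij,tj,ti->i", C, mu, Zc)) / T
        model.transition = A
        model.state_noise = Qn
        model.loadings = C
        model.noise_var = np.maximum(R, 1e-8)
        model.init_state_cov = V[0] + np.outer(mu[0], mu[0])
    model.loglik_curve = np.asarray(lls)
    model.converged = len(lls) < max_iter
    rho = np.max(np.abs(np.linalg.eigvals(model.transition)))
    if rho > 1.05:
        warnings.warn(f"unstable LDS transition (spectral radius {rho:.3f})", RuntimeWarning)
    return model


def estimate_states(model: LatentModel, Z: np.ndarray) -> np.ndarray:
    """Latent series for new data.

    PCA: projection onto components.  FA: posterior factor means.
    LDS: causal (filtered, not smoothed) state estimates — suitable as
    inputs to a real-time-style decoder.
    """
    Z = np.asarray(Z, float)
    if model.method == "pca":
        return (Z - model.mean) @ model.loadings[:, : model.q]
    if model.method == "fa":
        Zc = Z - model.mean
        L, psi = model.loadings, model.noise_var
        M = np.eye(model.q) + (L.T / psi) @ L
        return Zc @ (np.linalg.solve(M, L.T / psi)).T
    if model.method == "lds":
        mu_f, *_ = _kalman_filter(model, Z)
        return mu_f
    raise ValueError(f"unknown method {model.method!r}")


def reconstruct(model: LatentModel, Z: np.ndarray, q: int | None = None) -> np.ndarray:
    """Reconstruct rates from the first q latents (for model selection)."""
    q = model.q if q is None else q
    if model.method == "pca":
        W = model.loadings[:, :q]
        return (Z - model.mean) @ W @ W.T + model.mean
    states = estimate_states(model, Z)
    return states[:, : model.q] @ model.loadings.T + model.mean


def lno_reconstruction_error(model: LatentModel, Z: np.ndarray, q: int | None = None) -> float:
    """Leave-neuron-out reconstruction MAE.

    Each unit is predicted from the latents inferred from all *other*
    units.  Unlike plain projection reconstruction (which can only improve
    as q grows), this cross-validated error turns up once extra dimensions
    start fitting unit-private noise, so its minimum identifies the shared
    dimensionality.
    """
    Z = np.asarray(Z, float)
    q = model.q if q is None else q
    L = model.loadings[:, :q]
    m = L.shape[0]
    psi = model.noise_var if model.noise_var is not None else np.ones(m)
    with_prior = model.method in ("fa", "lds")  # posterior mean; PCA uses least squares
    Zc = Z - model.mean
    err = 0.0
    for j in range(m):
        mask = np.arange(m) != j
        Lm = L[mask]
        Lw = Lm / psi[mask][:, None]
        A = Lm.T @ Lw
        if with_prior:
            A = A + np.eye(q)
        else:
            A = A + 1e-10 * np.eye(q)
        scores = Zc[:, mask] @ np.linalg.solve(A, Lw.T).T
        err += np.mean(np.abs(Zc[:, j] - scores @ L[j]))
    return err / m


def pca_candidates(m: int, step: int = 5) -> list[int]:
    cands = list(range(step, m + 1, step))
    if not cands or cands[-1] != m:
        cands.append(m)
    return cands


def fa_lds_candidates(m: int, step: int = 5, cap: int = 40) -> list[int]:
    return list(range(step, min(m, cap) + 1, step))


def select_dimensionality(
    method: str,
    Z_train: np.ndarray,
    Z_test: np.ndarray,
    candidates,
    leave_neuron_out: bool = True,
    **fit_kwargs,
) -> tuple[int, dict]:
    """Pick q minimizing test-set reconstruction MAE.

    By default the error is leave-neuron-out (cross-validated across
    units), which has a minimum at the shared dimensionality; plain
    projection reconstruction (leave_neuron_out=False) is monotone in q
    for PCA and only useful as a sanity check.  PCA is fitted once
    (components are nested); FA and LDS are refitted per candidate.
    Returns (q_star, {q: mae}).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")

    def error(model, q=None):
        if leave_neuron_out:
            return lno_reconstruction_error(model, Z_test, q)
        return float(np.mean(np.abs(Z_test - reconstruct(model, Z_test, q))))

    maes = {}
    if method == "pca":
        model = fit_pca(Z_train)
        for q in candidates:
            maes[q] = error(model, min(q, model.q))
    elif method in ("fa", "lds"):
        fitter = fit_fa if method == "fa" else fit_lds
        for q in candidates:
            maes[q] = error(fitter(Z_train, q, **fit_kwargs))
    else:
        raise ValueError(f"unknown method {method!r}")
    q_star = min(maes, key=lambda q: (maes[q], q))
    return q_star, maes
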
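"""Deep canonical correlation analysis between firing rates and kinematics.

Two feedforward networks map the firing-rate view (m inputs) and the
kinematic view (3 inputs) to 3-dimensional outputs.  Training maximizes
the total canonical correlation of the network outputs — the sum of the
singular values of the whitened (covariance-regularized) cross-covariance
— minus a trade-off-weighted autoencoder reconstruction penalty and an L2
weight decay.  Hidden layers are initialized by greedy denoising-
autoencoder pretraining.  A final linear CCA on the network outputs
rotates them into ordered canonical pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cca import LinearCanonicalModel, canonical_correlations, fit_lcca, transform_lcca
from .nets import MLP, Adam, pretrain_dae

__all__ = [
    "DeepCanonicalModel",
    "DEFAULT_THETA",
    "THETA_RANGES",
    "validate_theta",
    "fit_dcca",
    "transform_dcca",
    "invert_dcca_velocity",
    "search_hyperparams",
]

# Hyperparameter schema.  Output width of both networks is fixed to 3
# (the number of kinematic variables, which caps the canonical pairs).
DEFAULT_THETA = {
    "n_nodes_z": 64,
    "n_layers_z": 2,
    "rcov_z": 0.04,
    "n_nodes_x": 32,
    "n_layers_x": 3,
    "rcov_x": 0.04,
    "batch_size": 4096,  # >= n -> full-batch gradients (least optimization noise)
    "ae_batch_size": 256,
    "l2": 5e-4,
    "eta": 2e-3,
    "lam": 1e-2,  # trade-off weight of the reconstruction penalty
    "epochs": 400,
    "dae_epochs": 5,
    "activation": "sigmoid",
}

# Admissible search ranges (used by validate_theta in strict mode and by
# the random hyperparameter search).
THETA_RANGES = {
    "n_nodes_z": [2**k for k in range(4, 11)],
    "n_nodes_x": [2**k for k in range(4, 11)],
    "n_layers_z": [1, 2, 3, 4],
    "n_layers_x": [1, 2, 3, 4],
    "batch_size": [2**k for k in range(5, 9)],
    "ae_batch_size": [2**k for k in range(5, 9)],
    "eta": [10.0**k for k in range(-5, -1)],
    "rcov_z": [10.0**k for k in range(-6, 0)],
    "rcov_x": [10.0**k for k in range(-6, 0)],
    "l2": [10.0**k for k in range(-6, 0)],
    "lam": [10.0**k for k in range(-6, 0)],
}

OUTPUT_DIM = 3


class IllConditionedError(Exception):
    """Output covariance is ill-conditioned; increase rcov."""


def validate_theta(theta: dict | None, strict: bool = False) -> dict:
    """Fill defaults; optionally enforce the documented search ranges."""
    th = dict(DEFAULT_THETA)
    if theta:
        unknown = set(theta) - set(DEFAULT_THETA)
        if unknown:
            raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")
        th.update(theta)
    if th["n_layers_z"] < 1 or th["n_layers_x"] < 1:
        raise ValueError("need at least one layer per view")
    if th["rcov_z"] < 0 or th["rcov_x"] < 0:
        raise ValueError("rcov must be >= 0")
    if strict:
        for key, grid in THETA_RANGES.items():
            if not (min(grid) <= th[key] <= max(grid)):
                raise ValueError(f"{key}={th[key]} outside admissible range")
    return th


@dataclass
class DeepCanonicalModel:
    """Fitted deep CCA: two encoder nets + output-layer linear CCA."""

    net_z: MLP
    net_x: MLP
    dec_z: MLP
    dec_x: MLP
    mean_z: np.ndarray
    std_z: np.ndarray
    mean_x: np.ndarray
    std_x: np.ndarray
    output_cca: LinearCanonicalModel
    theta: dict
    seed: int
    objective_curve: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def rho(self) -> np.ndarray:
        return self.output_cca.rho


def _corr_objective_and_grads(Hz, Hx, rz, rx, need_grads=True):
    """Total correlation of two output batches and its gradients.

    The objective is the sum of singular values of
    ``S11^{-1/2} S12 S22^{-1/2}`` with ``S11 = cov(Hz) + rz I`` etc.
    Gradients w.r.t. Hz and Hx follow the standard matrix calculus for
    singular-value sums of the whitened cross-covariance.
    """
    n = len(Hz)
    H1 = Hz - Hz.mean(axis=0)
    H2 = Hx - Hx.mean(axis=0)
    S11 = H1.T @ H1 / (n - 1) + rz * np.eye(H1.shape[1])
    S22 = H2.T @ H2 / (n - 1) + rx * np.eye(H2.shape[1])
    S12 = H1.T @ H2 / (n - 1)

    def inv_sqrt(S, label):
        w, V = np.linalg.eigh(S)
        if w.min() <= 1e-12 * max(w.max(), 1.0):
            raise IllConditionedError(
                f"{label} covariance ill-conditioned; increase rcov"
            )
        return (V / np.sqrt(w)) @ V.T

    K11 = inv_sqrt(S11, "Z-view")
    K22 = inv_sqrt(S22, "X-view")
    Tmat = K11 @ S12 @ K22
    U, s, Vt = np.linalg.svd(Tmat)
    corr = float(s.sum())
    if not need_grads:
        return corr, None, None
    d12 = K11 @ U @ Vt @ K22
    d11 = -0.5 * K11 @ (U * s) @ U.T @ K11
    d22 = -0.5 * K22 @ (Vt.T * s) @ Vt @ K22
    gH1 = (2 * H1 @ d11 + H2 @ d12.T) / (n - 1)
    gH2 = (2 * H2 @ d22 + H1 @ d12) / (n - 1)
    return corr, gH1, gH2


def fit_dcca(
    Z_train: np.ndarray,
    X_train: np.ndarray,
    theta: dict | None = None,
    seed: int = 0,
) -> DeepCanonicalModel:
    """Train a deep CCA model by minibatch gradient ascent.

    Both views are standardized with training statistics.  Hidden layers
    are DAE-pretrained; the full objective is
    ``total_corr - lam * (recon_z + recon_x) - l2 * ||W||^2`` optimized
    with Adam.  The training-set total correlation is monitored per epoch
    (stored in objective_curve) and the final model includes a linear CCA
    fitted on the network outputs.
    """
    th = validate_theta(theta)
    Z = np.asarray(Z_train, float)
    X = np.asarray(X_train, float)
    n, m = Z.shape
    rng = np.random.default_rng(seed)

    mean_z, std_z = Z.mean(axis=0), np.maximum(Z.std(axis=0), 1e-8)
    mean_x, std_x = X.mean(axis=0), np.maximum(X.std(axis=0), 1e-8)
    Zs = (Z - mean_z) / std_z
    Xs = (X - mean_x) / std_x

    sizes_z = [m] + [th["n_nodes_z"]] * th["n_layers_z"] + [OUTPUT_DIM]
    sizes_x = [X.shape[1]] + [th["n_nodes_x"]] * th["n_layers_x"] + [OUTPUT_DIM]
    act = th["activation"]
    net_z = MLP(sizes_z, activation=act, seed=seed)
    net_x = MLP(sizes_x, activation=act, seed=seed + 1)
    dec_z = MLP(sizes_z[::-1], activation=act, seed=seed + 2)
    dec_x = MLP(sizes_x[::-1], activation=act, seed=seed + 3)

    if th["dae_epochs"] > 0 and act == "sigmoid":
        for net, data, s in ((net_z, Zs, seed + 10), (net_x, Xs, seed + 11)):
            Ws, bs, _ = pretrain_dae(
                data,
                net.sizes[:-1],  # hidden stack only; output layer stays random
                epochs=th["dae_epochs"],
                batch_size=th["ae_batch_size"],
                lr=th["eta"],
                seed=s,
            )
            for l, (W, b) in enumerate(zip(Ws, bs)):
                net.W[l], net.b[l] = W, b

    params = net_z.params() + net_x.params() + dec_z.params() + dec_x.params()
    opt = Adam(params, lr=th["eta"])
    lam, l2 = th["lam"], th["l2"]
    batch = min(th["batch_size"], n)
    rz, rx = th["rcov_z"], th["rcov_x"]

    curve = []
    for epoch in range(th["epochs"]):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            if len(idx) < 2 * OUTPUT_DIM:  # too small for a covariance estimate
                continue
            Zb, Xb = Zs[idx], Xs[idx]
            acts_z = net_z.forward(Zb)
            acts_x = net_x.forward(Xb)
            Hz, Hx = acts_z[-1], acts_x[-1]
            corr, gHz, gHx = _corr_objective_and_grads(Hz, Hx, rz, rx)
            if not np.isfinite(corr):
                raise FloatingPointError(
                    f"non-finite DCCA objective at epoch {epoch}; "
                    f"last finite objective: {curve[-1] if curve else None}"
                )
            # reconstruction penalty: decoders map outputs back to inputs
            gdec_z, gHz_rec = _recon_backward(dec_z, Hz, Zb)
            gdec_x, gHx_rec = _recon_backward(dec_x, Hx, Xb)
            # loss = -corr + lam * recon; gradients descend the loss
            genc_z, _ = net_z.backward(acts_z, -gHz + lam * gHz_rec)
            genc_x, _ = net_x.backward(acts_x, -gHx + lam * gHx_rec)
            grads = genc_z + genc_x + [lam * g for g in gdec_z] + [lam * g for g in gdec_x]
            if l2 > 0:
                for g, p in zip(grads, params):
                    if p.ndim == 2:  # decay weights, not biases
                        g += 2 * l2 * p
            opt.step(grads)
        corr_full, _, _ = _corr_objective_and_grads(net_z(Zs), net_x(Xs), rz, rx, need_grads=False)
        curve.append(corr_full)

    Hz, Hx = net_z(Zs), net_x(Xs)
    # tiny fixed ridge: the stored rho must equal the Pearson correlation
    # of the rotated outputs (rcov is a training regularizer only)
    out_cca = fit_lcca(Hz, Hx, ridge=1e-8)
    model = DeepCanonicalModel(
        net_z=net_z,
        net_x=net_x,
        dec_z=dec_z,
        dec_x=dec_x,
        mean_z=mean_z,
        std_z=std_z,
        mean_x=mean_x,
        std_x=std_x,
        output_cca=out_cca,
        theta=th,
        seed=seed,
        objective_curve=np.asarray(curve),
    )
    return model


def _recon_backward(dec: MLP, H, target):
    acts = dec.forward(H)
    grad = 2.0 * (acts[-1] - target) / len(target)
    return dec.backward(acts, grad)


def transform_dcca(
    model: DeepCanonicalModel, Z: np.ndarray | None = None, X: np.ndarray | None = None
):
    """Deep canonical variables: forward pass + output CCA rotation."""
    Hz = Hx = None
    if Z is not None:
        Z = np.asarray(Z, float)
        if Z.shape[1] != len(model.mean_z):
            raise ValueError("Z has wrong number of units for this model")
        Hz = model.net_z((Z - model.mean_z) / model.std_z)
    if X is not None:
        X = np.asarray(X, float)
        if X.shape[1] != len(model.mean_x):
            raise ValueError("X has wrong number of kinematic variables")
        Hx = model.net_x((X - model.mean_x) / model.std_x)
    return transform_lcca(model.output_cca, Hz, Hx)


def invert_dcca_velocity(X_CV_hat: np.ndarray, model: DeepCanonicalModel, eps: float = 1e-6):
    """Map estimated kinematic canonical variables back to velocity.

    Inverts the output CCA rotation, then the kinematic network layer by
    layer: linear layers by pseudo-inverse, sigmoidal layers through the
    logit (outputs clipped to (eps, 1 - eps); clipping is counted and
    warned about).  Returns the (n, 2) velocity estimate.
    """
    cca = model.output_cca
    H = cca.mean_x + X_CV_hat @ np.linalg.pinv(cca.beta)
    net = model.net_x
    n_clipped = 0
    a = H
    for l in range(net.n_layers - 1, -1, -1):
        if l < net.n_layers - 1 and net.activation == "sigmoid":
            out_of_domain = (a <= eps) | (a >= 1 - eps)
            n_clipped += int(out_of_domain.sum())
            a = np.clip(a, eps, 1 - eps)
            a = np.log(a / (1 - a))  # logit
        a = (a - net.b[l]) @ np.linalg.pinv(net.W[l])
    if n_clipped:
        warnings.warn(
            f"{n_clipped} activations clipped to the logit domain during inversion",
            RuntimeWarning,
        )
    X_hat = a * model.std_x + model.mean_x
    return X_hat[:, :2]


def search_hyperparams(
    Z: np.ndarray,
    X: np.ndarray,
    space: dict | None = None,
    budget: int = 50,
    seed: int = 0,
    val_frac: float = 0.2,
    epochs: int = 30,
) -> tuple[dict, list]:
    """Budgeted random search over the DCCA hyperparameter space.

    Samples ``budget`` configurations uniformly from ``space`` (defaults
    to the documented ranges), trains each briefly on the chronological
    first (1 - val_frac) of the data, and scores by total canonical
    correlation on the held-out tail.  Deterministic given ``seed``.
    Returns (best_theta, trial_log).
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = {k: list(v) for k, v in (space or THETA_RANGES).items()}
    if any(len(v) == 0 for v in space.values()):
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    n = len(Z)
    n_train = int(n * (1 - val_frac))
    Zt, Xt = Z[:n_train], X[:n_train]
    Zv, Xv = Z[n_train:], X[n_train:]

    log = []
    best_theta, best_score = None, -np.inf
    for trial in range(budget):
        theta = {k: v[rng.integers(len(v))] for k, v in space.items()}
        theta.setdefault("epochs", epochs)
        theta.setdefault("dae_epochs", min(5, DEFAULT_THETA["dae_epochs"]))
        try:
            model = fit_dcca(Zt, Xt, theta, seed=seed + 1000 + trial)
            U, V = transform_dcca(model, Zv, Xv)
            score = float(np.sum(canonical_correlations(U, V)))
        except (IllConditionedError, FloatingPointError):
            score = -np.inf
        log.append((theta, score))
        if score > best_score:
            best_theta, best_score = theta, score
    return best_theta, log
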
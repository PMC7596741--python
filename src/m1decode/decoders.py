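"""Decoders mapping neural representations to hand velocity.

Three decoders:

* a steady-state linear Kalman filter (LKF) with kinematic state
  [vx, vy, speed], state reset to zero at each trial start after the gain
  has converged to its Riccati fixed point;
* a neural dynamical filter (NDF): ridge regression from latent LDS
  states directly to kinematics (used instead of the LKF when the
  representation already carries its own dynamics);
* a single-layer LSTM regressor trained per-trial with Adam, hidden state
  reset at trial starts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KalmanModel",
    "LstmModel",
    "fit_lkf",
    "run_lkf",
    "run_lkf_time_varying",
    "fit_ndf",
    "run_ndf",
    "fit_lstm",
    "run_lstm",
    "lstm_step",
]


# ---------------------------------------------------------------------------
# Linear Kalman filter
# ---------------------------------------------------------------------------


@dataclass
class KalmanModel:
    """State-space decoder: x_t = A x_{t-1} + a0 + w,  o_t = H x_t + h0 + v.

    State is [vx, vy, speed]; the affine offsets a0/h0 absorb the nonzero
    mean of speed.  K_inf is the steady-state Kalman gain (Riccati fixed
    point) so that each trial can be filtered from x_0 = 0 with a constant
    gain.
    """

    A: np.ndarray  # (3, 3)
    a0: np.ndarray  # (3,)
    H: np.ndarray  # (p, 3)
    h0: np.ndarray  # (p,)
    Q: np.ndarray  # (3, 3)
    V: np.ndarray  # (p, p)
    K_inf: np.ndarray  # (3, p)
    extras: dict = field(default_factory=dict)


def _lagged_pairs(X, trial_of_bin):
    """Indices (t-1, t) of within-trial consecutive bins."""
    t = np.arange(1, len(X))
    same = trial_of_bin[1:] == trial_of_bin[:-1] if trial_of_bin is not None else np.ones(len(t), bool)
    return t[same] - 1, t[same]

def _affine_lstsq(Y, X):
    """Least squares Y ~= X @ B.T + b0; returns (B, b0, residual cov)."""
    design = np.column_stack([X, np.ones(len(X))])
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    B, b0 = coef[:-1].T, coef[-1]
    resid = Y - X @ B.T - b0
    cov = resid.T @ resid / max(len(Y) - X.shape[1] - 1, 1)
    return B, b0, (cov + cov.T) / 2


def fit_lkf(
    X_train: np.ndarray,
    O_train: np.ndarray,
    trial_of_bin: np.ndarray | None = None,
    gain_tol: float = 1e-10,
    max_iter: int = 10_000,
) -> KalmanModel:
    """Fit the LKF from aligned kinematic states and observations.

    A and H are least-squares fits; Q and V their residual covariances;
    the steady-state gain is obtained by iterating the Riccati recursion
    until the gain changes by < gain_tol in max norm.
    """
    X = np.asarray(X_train, float)
    O = np.asarray(O_train, float)
    if len(X) != len(O):
        raise ValueError("states and observations must be aligned")
    prev, nxt = _lagged_pairs(X, trial_of_bin)
    A, a0, Q = _affine_lstsq(X[nxt], X[prev])
    H, h0, V = _affine_lstsq(O, X)

    d = X.shape[1]
    P = Q.copy()
    K = np.zeros((d, O.shape[1]))
    Id = np.eye(d)
    for it in range(max_iter):
        P_pred = A @ P @ A.T + Q
        S = H @ P_pred @ H.T + V
        K_new = np.linalg.solve(S.T, (P_pred @ H.T).T).T
        P = (Id - K_new @ H) @ P_pred
        if np.max(np.abs(K_new - K)) < gain_tol:
            K = K_new
            break
        K = K_new
    else:
        ev = np.abs(np.linalg.eigvals(A))
        raise RuntimeError(
            f"Riccati gain did not converge in {max_iter} iterations "
            f"(|eig(A)| in [{ev.min():.3f}, {ev.max():.3f}])"
        )
    return KalmanModel(A=A, a0=a0, H=H, h0=h0, Q=Q, V=V, K_inf=K)


def run_lkf(model: KalmanModel, O_test: np.ndarray, trial_of_bin: np.ndarray) -> np.ndarray:
    """Steady-state Kalman filtering; state reset to 0 at every trial start.

    Returns the (n, 2) decoded velocity (the speed component is dropped).
    """
    O = np.asarray(O_test, float)
    trial_of_bin = np.asarray(trial_of_bin)
    if len(O) == 0:
        return np.zeros((0, 2))
    preds = np.empty((len(O), model.A.shape[0]))
    x = np.zeros(model.A.shape[0])
    prev_trial = None
    for t in range(len(O)):
        if trial_of_bin[t] != prev_trial:
            x = np.zeros_like(x)
            prev_trial = trial_of_bin[t]
        x_pred = model.A @ x + model.a0
        x = x_pred + model.K_inf @ (O[t] - model.H @ x_pred - model.h0)
        preds[t] = x
    return preds[:, :2]


def run_lkf_time_varying(model: KalmanModel, O_test: np.ndarray) -> np.ndarray:
    """Classic time-varying Kalman filter (no resets) — reference filter
    used to check that the steady-state gain has genuinely converged."""
    O = np.asarray(O_test, float)
    d = model.A.shape[0]
    x = np.zeros(d)
    P = model.Q.copy()
    preds = np.empty((len(O), d))
    Id = np.eye(d)
    for t in range(len(O)):
        x_pred = model.A @ x + model.a0
        P_pred = model.A @ P @ model.A.T + model.Q
        S = model.H @ P_pred @ model.H.T + model.V
        K = np.linalg.solve(S.T, (P_pred @ model.H.T).T).T
        x = x_pred + K @ (O[t] - model.H @ x_pred - model.h0)
        P = (Id - K @ model.H) @ P_pred
        preds[t] = x
    return preds[:, :2]


# ---------------------------------------------------------------------------
# Neural dynamical filter: ridge regression from latent states
# ---------------------------------------------------------------------------


def fit_ndf(latent_train: np.ndarray, X_train: np.ndarray, ridge: float = 1e-6):
    """Ridge regression latent -> [vx, vy, speed]; returns (B, b0)."""
    L = np.asarray(latent_train, float)
    X = np.asarray(X_train, float)
    mean_l, mean_x = L.mean(axis=0), X.mean(axis=0)
    Lc = L - mean_l
    G = Lc.T @ Lc + ridge * np.eye(L.shape[1])
    if ridge == 0 and np.linalg.cond(G) > 1e12:
        raise np.linalg.LinAlgError("singular design; pass ridge > 0")
    B = np.linalg.solve(G, Lc.T @ (X - mean_x))
    b0 = mean_x - mean_l @ B
    return B, b0


def run_ndf(ndf_map, latent_test: np.ndarray) -> np.ndarray:
    """Apply the linear map; returns (n, 2) velocity."""
    B, b0 = ndf_map
    return (np.asarray(latent_test, float) @ B + b0)[:, :2]


# ---------------------------------------------------------------------------
# LSTM regressor
# ---------------------------------------------------------------------------

GATES = ("f", "i", "o", "c")


@dataclass
class LstmModel:
    """Single-layer LSTM + linear velocity readout.

    Per gate g in {f, i, o, c}: W_in[g] (d, l), W_rec[g] (l, l), b[g] (l,).
    Forget/input/output gates are sigmoidal; the candidate cell and the
    cell output squash through tanh.
    """

    W_in: dict
    W_rec: dict
    b: dict
    W_out: np.ndarray  # (l, 2)
    b_out: np.ndarray  # (2,)
    mean_in: np.ndarray
    std_in: np.ndarray
    hidden: int
    theta: dict = field(default_factory=dict)
    loss_curve: np.ndarray | None = None

    def params(self):
        return (
            [self.W_in[g] for g in GATES]
            + [self.W_rec[g] for g in GATES]
            + [self.b[g] for g in GATES]
            + [self.W_out, self.b_out]
        )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def lstm_step(model: LstmModel, y_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray):
    """One LSTM update. Returns (h, c, gates) with gates kept for BPTT."""
    W, R, b = model.W_in, model.W_rec, model.b
    f = _sigmoid(y_t @ W["f"] + h_prev @ R["f"] + b["f"])
    i = _sigmoid(y_t @ W["i"] + h_prev @ R["i"] + b["i"])
    o = _sigmoid(y_t @ W["o"] + h_prev @ R["o"] + b["o"])
    cu = np.tanh(y_t @ W["c"] + h_prev @ R["c"] + b["c"])
    c = f * c_prev + i * cu
    h = o * np.tanh(c)
    return h, c, (f, i, o, cu)


def _forward_seq(model, Y):
    """Forward a (T, d) sequence from zero state; returns caches for BPTT."""
    T = len(Y)
    l = model.hidden
    h = np.zeros((T + 1, l))
    c = np.zeros((T + 1, l))
    gates = []
    for t in range(T):
        h[t + 1], c[t + 1], g = lstm_step(model, Y[t], h[t], c[t])
        gates.append(g)
    pred = h[1:] @ model.W_out + model.b_out
    return pred, h, c, gates


def _backward_seq(model, Y, pred, target, h, c, gates):
    """BPTT for squared-error loss on one sequence; returns param grads."""
    T, l = len(Y), model.hidden
    gW_in = {g: np.zeros_like(model.W_in[g]) for g in GATES}
    gW_rec = {g: np.zeros_like(model.W_rec[g]) for g in GATES}
    gb = {g: np.zeros_like(model.b[g]) for g in GATES}
    d_out = 2.0 * (pred - target) / target.size
    gW_out = h[1:].T @ d_out
    gb_out = d_out.sum(axis=0)

    dh_next = np.zeros(l)
    dc_next = np.zeros(l)
    for t in range(T - 1, -1, -1):
        f, i, o, cu = gates[t]
        tanh_c = np.tanh(c[t + 1])
        dh = d_out[t] @ model.W_out.T + dh_next
        do = dh * tanh_c
        dc = dh * o * (1 - tanh_c**2) + dc_next
        df = dc * c[t]
        di = dc * cu
        dcu = dc * i
        dc_next = dc * f
        pre = {
            "f": df * f * (1 - f),
            "i": di * i * (1 - i),
            "o": do * o * (1 - o),
            "c": dcu * (1 - cu**2),
        }
        dh_next = np.zeros(l)
        for g in GATES:
            gW_in[g] += np.outer(Y[t], pre[g])
            gW_rec[g] += np.outer(h[t], pre[g])
            gb[g] += pre[g]
            dh_next += pre[g] @ model.W_rec[g].T
    return (
        [gW_in[g] for g in GATES]
        + [gW_rec[g] for g in GATES]
        + [gb[g] for g in GATES]
        + [gW_out, gb_out]
    )


DEFAULT_LSTM_THETA = {
    "hidden": 32,
    "minibatch": 16,  # trials per gradient step
    "rcov": 1e-4,  # L2 regularization on weights
    "eta": 1e-2,
    "epochs": 100,
    "patience": 10,
    "val_frac": 0.1,
    "grad_clip": 5.0,
    "beta1": 0.95,  # gradient decay factor
    "beta2": 0.99,  # squared-gradient decay factor
}


class _Adam:
    def __init__(self, params, lr, beta1, beta2, eps=1e-8):
        self.params, self.lr, self.b1, self.b2, self.eps = params, lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / (1 - self.b1**self.t)) / (
                np.sqrt(v / (1 - self.b2**self.t)) + self.eps
            )


def _split_sequences(Y, X, trial_of_bin):
    seqs = []
    for tr in np.unique(trial_of_bin):
        rows = trial_of_bin == tr
        seqs.append((Y[rows], X[rows]))
    return seqs


def fit_lstm(
    Y_train: np.ndarray,
    X_train: np.ndarray,
    trial_of_bin: np.ndarray,
    theta: dict | None = None,
    seed: int = 0,
) -> LstmModel:
    """Train the LSTM velocity regressor.

    Sequences are trials (hidden state restarts at each trial).  Training
    uses Adam (gradient decay 0.95, squared-gradient decay 0.99) on
    squared-error loss, trial minibatches shuffled every epoch, gradient
    clipping, and early stopping when the inner-validation loss stops
    improving.  Deterministic given ``seed``.
    """
    th = dict(DEFAULT_LSTM_THETA)
    if theta:
        unknown = set(theta) - set(DEFAULT_LSTM_THETA)
        if unknown:
            raise ValueError(f"unknown LSTM hyperparameters: {sorted(unknown)}")
        th.update(theta)
    rng = np.random.default_rng(seed)
    Y = np.asarray(Y_train, float)
    X = np.asarray(X_train, float)[:, :2]  # velocity targets only
    mean_in, std_in = Y.mean(axis=0), np.maximum(Y.std(axis=0), 1e-8)
    Ys = (Y - mean_in) / std_in

    l, d = th["hidden"], Y.shape[1]
    if l < 1:
        raise ValueError("hidden size must be >= 1")
    lim = np.sqrt(6.0 / (d + l))
    limr = np.sqrt(6.0 / (2 * l))
    model = LstmModel(
        W_in={g: rng.uniform(-lim, lim, (d, l)) for g in GATES},
        W_rec={g: rng.uniform(-limr, limr, (l, l)) for g in GATES},
        b={g: np.zeros(l) for g in GATES},
        W_out=rng.uniform(-np.sqrt(6.0 / (l + 2)), np.sqrt(6.0 / (l + 2)), (l, 2)),
        b_out=np.zeros(2),
        mean_in=mean_in,
        std_in=std_in,
        hidden=l,
        theta=th,
    )
    seqs = _split_sequences(Ys, X, np.asarray(trial_of_bin))
    n_val = max(1, int(round(th["val_frac"] * len(seqs)))) if len(seqs) > 3 else 0
    train_seqs = seqs[: len(seqs) - n_val] if n_val else seqs
    val_seqs = seqs[len(seqs) - n_val :] if n_val else seqs

    def dataset_loss(ss):
        tot, cnt = 0.0, 0
        for Yt, Xt in ss:
            pred, *_ = _forward_seq(model, Yt)
            tot += np.sum((pred - Xt) ** 2)
            cnt += Xt.size
        return tot / cnt

    params = model.params()
    opt = _Adam(params, th["eta"], th["beta1"], th["beta2"])
    best_val, best_snapshot, stale = np.inf, None, 0
    losses = []
    for epoch in range(th["epochs"]):
        order = rng.permutation(len(train_seqs))
        for start in range(0, len(order), th["minibatch"]):
            batch = order[start : start + th["minibatch"]]
            grads = [np.zeros_like(p) for p in params]
            for j in batch:
                Yt, Xt = train_seqs[j]
                pred, h, c, gates = _forward_seq(model, Yt)
                if not np.all(np.isfinite(pred)):
                    raise FloatingPointError(
                        f"LSTM diverged at epoch {epoch}; last loss "
                        f"{losses[-1] if losses else None}"
                    )
                for g, gg in zip(grads, _backward_seq(model, Yt, pred, Xt, h, c, gates)):
                    g += gg / len(batch)
            if th["rcov"] > 0:
                for g, p in zip(grads, params):
                    if p.ndim == 2:
                        g += 2 * th["rcov"] * p
            norm = np.sqrt(sum(np.sum(g * g) for g in grads))
            if norm > th["grad_clip"]:
                grads = [g * (th["grad_clip"] / norm) for g in grads]
            opt.step(grads)
        val = dataset_loss(val_seqs)
        losses.append(val)
        if val < best_val * (1 - 0.001):
            best_val, stale = val, 0
            best_snapshot = [p.copy() for p in params]
        else:
            stale += 1
            if stale >= th["patience"]:
                break
    if best_snapshot is not None:
        for p, s in zip(params, best_snapshot):
            p[...] = s
    model.loss_curve = np.asarray(losses)
    return model


def run_lstm(model: LstmModel, Y_test: np.ndarray, trial_of_bin: np.ndarray) -> np.ndarray:
    """Stateful per-trial forward pass; hidden state resets at trial starts."""
    Y = np.asarray(Y_test, float)
    if Y.shape[1] != len(model.mean_in):
        raise ValueError("feature width mismatch")
    Ys = (Y - model.mean_in) / model.std_in
    trial_of_bin = np.asarray(trial_of_bin)
    out = np.empty((len(Y), 2))
    for tr in np.unique(trial_of_bin):
        rows = np.flatnonzero(trial_of_bin == tr)
        pred, *_ = _forward_seq(model, Ys[rows])
        out[rows] = pred
    return out
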
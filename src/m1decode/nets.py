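"""Small feedforward networks with hand-written backpropagation.

Plain-NumPy building blocks used by the deep CCA front-ends: a
fully-connected network with sigmoidal hidden layers and a linear output
layer, an Adam optimizer, and greedy layerwise denoising-autoencoder
pretraining with masking noise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam", "pretrain_dae"]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class MLP:
    """Fully connected net: sizes[0] -> ... -> sizes[-1].

    Hidden layers use ``activation`` ("sigmoid" or "identity"); the output
    layer is always linear.  Weights are Glorot-uniform, seeded.
    """

    def __init__(self, sizes, activation: str = "sigmoid", seed: int = 0):
        if activation not in ("sigmoid", "identity"):
            raise ValueError(f"unknown activation {activation!r}")
        self.sizes = list(sizes)
        self.activation = activation
        rng = np.random.default_rng(seed)
        self.W, self.b = [], []
        for d_in, d_out in zip(sizes[:-1], sizes[1:]):
            lim = np.sqrt(6.0 / (d_in + d_out))
            self.W.append(rng.uniform(-lim, lim, size=(d_in, d_out)))
            self.b.append(np.zeros(d_out))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def params(self):
        return self.W + self.b

    def _act(self, x):
        return _sigmoid(x) if self.activation == "sigmoid" else x

    def forward(self, X):
        """Returns the list of layer outputs [X, a_1, ..., a_L]."""
        acts = [np.asarray(X, float)]
        for l in range(self.n_layers):
            pre = acts[-1] @ self.W[l] + self.b[l]
            acts.append(pre if l == self.n_layers - 1 else self._act(pre))
        return acts

    def __call__(self, X):
        return self.forward(X)[-1]

    def backward(self, acts, grad_out):
        """Backprop a gradient w.r.t. the output through the net.

        Returns (gradients aligned with params(), gradient w.r.t. input).
        """
        gW = [None] * self.n_layers
        gb = [None] * self.n_layers
        delta = np.asarray(grad_out, float)
        for l in range(self.n_layers - 1, -1, -1):
            gW[l] = acts[l].T @ delta
            gb[l] = delta.sum(axis=0)
            delta = delta @ self.W[l].T
            if l > 0 and self.activation == "sigmoid":
                delta = delta * acts[l] * (1.0 - acts[l])
        return gW + gb, delta


class Adam:
    """Adam optimizer over a flat list of parameter arrays (in-place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def pretrain_dae(
    view_data: np.ndarray,
    layer_sizes,
    noise_frac: float = 0.2,
    epochs: int = 20,
    batch_size: int = 256,
    lr: float = 1e-3,
    activation: str = "sigmoid",
    seed: int = 0,
):
    """Greedy layerwise denoising-autoencoder pretraining.

    For each hidden layer in turn, a one-hidden-layer autoencoder is
    trained to reconstruct its (clean) input from a masked copy
    (entries zeroed with probability ``noise_frac``); the learned encoder
    weights initialize that layer.  Returns (weights, biases, losses)
    where losses is a list of (initial, final) reconstruction MSE per
    layer.
    """
    rng = np.random.default_rng(seed)
    data = np.asarray(view_data, float)
    Ws, bs, losses = [], [], []
    for l, (d_in, d_out) in enumerate(zip(layer_sizes[:-1], layer_sizes[1:])):
        ae = MLP([d_in, d_out, d_in], activation=activation, seed=seed + 101 * l)
        opt = Adam(ae.params(), lr=lr)
        n = len(data)

        def recon_mse():
            return float(np.mean((ae(data) - data) ** 2))

        loss0 = recon_mse()
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                clean = data[idx]
                noisy = clean * (rng.random(clean.shape) >= noise_frac)
                acts = ae.forward(noisy)
                grad = 2.0 * (acts[-1] - clean) / len(idx)
                grads, _ = ae.backward(acts, grad)
                opt.step(grads)
        losses.append((loss0, recon_mse()))
        Ws.append(ae.W[0].copy())
        bs.append(ae.b[0].copy())
        # next layer trains on this layer's codes
        data = ae._act(data @ ae.W[0] + ae.b[0]) if activation == "sigmoid" else data @ ae.W[0] + ae.b[0]
    return Ws, bs, losses
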
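"""Constructed benchmark conditions used by the test suite and scripts.

These fix, in one place, the synthetic study conditions under which the
stack's headline properties are demonstrated:

* a two-view benchmark where one view is an elementwise-squashed linear
  map of the other — the regime where a deep canonical front-end must
  beat the linear one;
* a strongly nonlinear reaching-session family (small ensemble, low
  baselines, deep modulation, all tuned units saturating) where a linear
  population readout of velocity is measurably suboptimal, so the
  representation ordering DCV <= LCV <= E-FR on Kalman decoding error is
  expected.  With milder mixtures, population averaging over diverse
  preferred directions linearizes the code and deep and linear canonical
  representations tie on velocity error.
"""

from __future__ import annotations

import numpy as np

from . import cca, dcca, decoders, evaluation, preprocess, synth
from .session import split_trials

__all__ = [
    "nonlinear_two_view_data",
    "NONLINEAR_SESSION_CONFIG",
    "ORDERING_THETA",
    "ordering_experiment",
]

# Strongly nonlinear reaching sessions: near-binary direction-selective
# units (rectification + saturation bite hard at 2-6 Hz baselines with
# 2-4 Hz/(cm/s) modulation), small ensemble so population averaging
# cannot linearize the code.
NONLINEAR_SESSION_CONFIG = {
    "n_units": 14,
    "n_trials": 120,
    "frac_nonlinear": 1.0,
    "rate_params": {
        "baseline_hz": (2.0, 6.0),
        "depth_hz_per_cms": (2.0, 4.0),
        "speed_gain": (0.0, 0.1),
    },
}

# Desk-scale deep-CCA settings for the ordering experiment: heavy
# covariance regularization, networks sized to a 14-unit ensemble, and
# full-batch training for low optimization noise.
ORDERING_THETA = {
    "n_nodes_z": 32,
    "n_layers_z": 2,
    "n_nodes_x": 16,
    "n_layers_x": 3,
    "epochs": 400,
    "dae_epochs": 5,
    "batch_size": 4096,
    "eta": 2e-3,
    "lam": 1e-2,
    "l2": 5e-4,
    "rcov_z": 0.04,
    "rcov_x": 0.04,
}


def nonlinear_two_view_data(n: int = 20000, m: int = 8, seed: int = 3):
    """Two views with a genuinely nonlinear cross-view map.

    z is Gaussian; x = tanh(2 * Mz / sqrt(m)) + small noise.  Returns
    (Z, X) — a linear CCA leaves correlation on the table here that a
    deep front-end recovers.
    """
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, m))
    M = rng.normal(size=(m, 3))
    X = np.tanh(2.0 * (Z @ M) / np.sqrt(m)) + 0.05 * rng.normal(size=(n, 3))
    return Z, X


def ordering_experiment(seed: int, theta: dict | None = None, config: dict | None = None) -> dict:
    """One seeded run of the representation-ordering experiment.

    Generates a strongly nonlinear session, preprocesses it, and decodes
    test-set velocity with the steady-state Kalman filter from three
    representations: the full smoothed rates (E-FR), the linear canonical
    variables (LCV) and the deep canonical variables (DCV).  Returns the
    mean per-trial velocity error for each.
    """
    theta = dict(ORDERING_THETA, **(theta or {}))
    session, _ = synth.make_synthetic_session(config or NONLINEAR_SESSION_CONFIG, seed=seed)
    binned = preprocess.make_binned(session)
    split = split_trials(session, 0.75)
    tr = binned.rows_for_trials(split.train_ids)
    te = binned.rows_for_trials(split.test_ids)
    fits = preprocess.fit_tuning_table(binned, split.train_ids)
    kept = preprocess.select_units(fits)
    Z = binned.Z[:, kept]
    Z_tr, X_tr, Z_te, X_te = Z[tr], binned.X[tr], Z[te], binned.X[te]
    t_tr, t_te = binned.trial_of_bin[tr], binned.trial_of_bin[te]

    def lkf_error(R_tr, R_te):
        lkf = decoders.fit_lkf(X_tr, R_tr, t_tr)
        pred = decoders.run_lkf(lkf, R_te, t_te)
        return float(evaluation.decoding_error(X_te[:, :2], pred, t_te).mean())

    errs = {"efr": lkf_error(Z_tr, Z_te)}
    lc = cca.fit_lcca(Z_tr, X_tr)
    errs["lcv"] = lkf_error(cca.transform_lcca(lc, Z_tr)[0], cca.transform_lcca(lc, Z_te)[0])
    dm = dcca.fit_dcca(Z_tr, X_tr, theta, seed=seed)
    errs["dcv"] = lkf_error(dcca.transform_dcca(dm, Z_tr)[0], dcca.transform_dcca(dm, Z_te)[0])
    return errs
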
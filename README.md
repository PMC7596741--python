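# m1decode

Offline benchmarking of kinematic decoders for intracortical brain–machine
interfaces. The package extracts *kinematics-coupled canonical
representations* of primary-motor-cortex (M1) population firing — by linear
and deep canonical correlation analysis — alongside the standard
unsupervised representations (PCA, factor analysis, linear-dynamical-system
latent states), and decodes 2D hand velocity from each of them with a
steady-state linear Kalman filter, a neural dynamical filter, or an LSTM
regressor. A synthetic reaching-session simulator with known ground-truth
tuning makes the entire stack testable without any recorded data.

It is written for neural-engineering researchers who want to compare
representation/decoder combinations under controlled conditions, or to sanity
check a decoding pipeline before pointing it at real recordings.

## The core method

Let z ∈ ℝ^m be the smoothed square-root firing rates of m units in a 50 ms
bin and x = (v_x, v_y, ‖v‖) the hand velocity and speed. Linear CCA seeks
coefficient pairs (α_k, β_k) maximizing

    ρ_k = corr(α_kᵀ z̄, β_kᵀ x̄),   αᵀ Σ_Z α = βᵀ Σ_X β = 1,

solved by whitening both views and taking the SVD of the whitened
cross-covariance; with 3 kinematic variables there are exactly
k = min(m, 3) = 3 canonical pairs. The neural canonical variables
Z_LCV = αᵀz̄ form a 3-dimensional representation maximally correlated with
kinematics.

Deep CCA replaces the linear maps with feedforward networks f_Z and f_X
(sigmoidal hidden layers, linear 3-unit outputs, denoising-autoencoder
pretraining) trained to maximize the total canonical correlation of the
outputs — the sum of singular values of the regularized whitened
cross-covariance — minus an autoencoder reconstruction penalty (weight λ)
and L2 decay. A final linear CCA on the network outputs orders the deep
canonical variables Z_DCV.

Each representation (raw rates E-FR, PCA, FA, LDS states, Z_LCV, Z_DCV) is
decoded by a linear Kalman filter with state x_t = (v_x, v_y, ‖v‖):

    x_t = A x_{t−1} + w,   o_t = H x_t + q,

run with the steady-state gain K∞ (the Riccati fixed point) and state reset
to zero at each trial start; LDS states use a direct ridge regression
(neural dynamical filter) instead, and an LSTM regressor provides the
nonlinear direct-decoding comparison. Decoding error is the per-trial mean
Euclidean distance between true and predicted velocity (and between true
and integrated positions).

## Worked example

```python
import numpy as np
from m1decode import synth, preprocess, cca, decoders, evaluation
from m1decode.session import split_trials

session, truth = synth.make_synthetic_session({"n_units": 30, "n_trials": 80}, seed=0)
binned = preprocess.make_binned(session, bin_s=0.05, smooth_sd_s=0.08)
split = split_trials(session, train_frac=0.75)

fits = preprocess.fit_tuning_table(binned, split.train_ids)
kept = preprocess.select_units(fits, threshold=0.01)
print(f"kept {len(kept)}/{session.n_units} units (tuning r^2 > 0.01)")

train = binned.rows_for_trials(split.train_ids)
test = binned.rows_for_trials(split.test_ids)
Z, X = binned.Z[:, kept], binned.X

model = cca.fit_lcca(Z[train], X[train])
U, V = cca.transform_lcca(model, Z[test], X[test])
print("test canonical correlations:", np.round(cca.canonical_correlations(U, V), 3))

lkf = decoders.fit_lkf(X[train], cca.transform_lcca(model, Z[train])[0], binned.trial_of_bin[train])
pred = decoders.run_lkf(lkf, U, binned.trial_of_bin[test])
err = evaluation.decoding_error(X[test, :2], pred, binned.trial_of_bin[test])
r, _ = evaluation.correlation_metrics(X[test, :2], pred)
print(f"velocity error: {err.mean():.2f} +/- {err.std():.2f} cm/s   corr (x, y): {np.round(r, 2)}")
```

prints

```
kept 30/30 units (tuning r^2 > 0.01)
test canonical correlations: [0.944 0.941 0.47 ]
velocity error: 3.78 +/- 0.60 cm/s   corr (x, y): [0.96 0.97]
```

The first two canonical pairs carry the velocity components (test ρ ≈ 0.94);
the third pair tracks speed, which a linear projection of a half-saturating
population captures only weakly (ρ ≈ 0.47). The Kalman decode of the three
canonical variables reaches per-trial velocity errors of ≈3.8 cm/s against
reach peak speeds of 25 cm/s, with x/y correlations of 0.96–0.97.

The same pipeline is scriptable from the shell:

```
m1decode simulate --seed 3 --out session.h5
m1decode preprocess session.h5 --bin-ms 50 --smooth-sd-ms 80 --out binned.csv
m1decode represent binned.csv --method lcca --out lcca.pkl --rho-out rho.csv
m1decode decode binned.csv --decoder lkf --representation lcca.pkl --out pred.csv
m1decode run-all --config config.yaml --out outdir     # full grid + manifest
```

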
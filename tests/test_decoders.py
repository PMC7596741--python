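import math

import numpy as np
import pytest

from m1decode.decoders import (
    fit_lkf,
    fit_lstm,
    fit_ndf,
    lstm_step,
    run_lkf,
    run_lkf_time_varying,
    run_lstm,
    run_ndf,
)


def _simulate_state_space(rng, A, H, Q, V, n):
    d, p = A.shape[0], H.shape[0]
    X = np.zeros((n, d))
    O = np.zeros((n, p))
    x = np.zeros(d)
    for t in range(n):
        x = A @ x + rng.multivariate_normal(np.zeros(d), Q)
        X[t] = x
        O[t] = H @ x + rng.multivariate_normal(np.zeros(p), V)
    return X, O


def _known_system(rng):
    A = np.array([[0.9, 0.05, 0.0], [-0.05, 0.9, 0.0], [0.0, 0.0, 0.8]])
    H = rng.normal(size=(6, 3))
    return A, H, 0.02 * np.eye(3), 0.05 * np.eye(6)


def test_lkf_parameter_recovery(rng):
    A, H, Q, V = _known_system(rng)
    X, O = _simulate_state_space(rng, A, H, Q, V, 50000)
    model = fit_lkf(X, O)
    scale_A, scale_H = np.abs(A).max(), np.abs(H).max()
    assert np.abs(model.A - A).max() / scale_A < 0.05
    assert np.abs(model.H - H).max() / scale_H < 0.05
    assert np.abs(model.Q - Q).max() / 0.02 < 0.05
    assert np.abs(model.V - V).max() / 0.05 < 0.05


def test_steady_state_matches_time_varying_filter(rng):
    A, H, Q, V = _known_system(rng)
    X, O = _simulate_state_space(rng, A, H, Q, V, 2000)
    model = fit_lkf(X, O)
    steady = run_lkf(model, O[:500], np.zeros(500, int))
    varying = run_lkf_time_varying(model, O[:500])
    assert np.abs(steady[50:] - varying[50:]).max() < 1e-6


def test_lkf_noiseless_limit_inverts_observation(rng):
    """V -> 0 with invertible H: the filter output approaches H^-1 o."""
    A = 0.95 * np.eye(3)
    H = rng.normal(size=(3, 3)) + 2 * np.eye(3)
    Q = 0.05 * np.eye(3)
    V = 1e-10 * np.eye(3)
    X, O = _simulate_state_space(rng, A, H, Q, V, 3000)
    model = fit_lkf(X, O)
    pred = run_lkf(model, O, np.zeros(len(O), int))
    expected = (np.linalg.solve(H, (O - model.h0).T).T)[:, :2]
    assert np.abs(pred[20:] - expected[20:]).max() < 1e-3


def test_lkf_trial_resets_and_empty_input(rng):
    A, H, Q, V = _known_system(rng)
    X, O = _simulate_state_space(rng, A, H, Q, V, 5000)
    model = fit_lkf(X, O)
    assert run_lkf(model, np.zeros((0, 6)), np.zeros(0, int)).shape == (0, 2)
    # single-bin trials: every output is the steady gain applied to the
    # innovation from the zero state
    O_test = O[:10]
    trials = np.arange(10)
    pred = run_lkf(model, O_test, trials)
    x_pred = model.a0  # A @ 0 + a0
    expected = x_pred + (model.K_inf @ (O_test - model.H @ x_pred - model.h0).T).T
    np.testing.assert_allclose(pred, expected[:, :2], atol=1e-12)


def test_lkf_is_causal(rng):
    A, H, Q, V = _known_system(rng)
    X, O = _simulate_state_space(rng, A, H, Q, V, 3000)
    model = fit_lkf(X, O)
    trials = np.repeat(np.arange(10), 30)
    O_test = O[:300].copy()
    base = run_lkf(model, O_test, trials)
    O_test[200:] += 100.0
    altered = run_lkf(model, O_test, trials)
    np.testing.assert_array_equal(base[:200], altered[:200])


def test_ndf_identity_and_limits(rng):
    states = rng.normal(size=(500, 3))
    B, b0 = fit_ndf(states, states)
    np.testing.assert_allclose(B, np.eye(3), atol=1e-6)
    np.testing.assert_allclose(run_ndf((B, b0), states), states[:, :2], atol=1e-6)
    B_inf, _ = fit_ndf(states, states, ridge=1e12)
    assert np.abs(B_inf).max() < 1e-6


def test_ndf_matches_normal_equations_oracle(rng):
    L = rng.normal(size=(400, 5))
    X = rng.normal(size=(400, 3))
    ridge = 0.1
    B, b0 = fit_ndf(L, X, ridge=ridge)
    Lc = L - L.mean(0)
    Xc = X - X.mean(0)
    B_oracle = np.linalg.solve(Lc.T @ Lc + ridge * np.eye(5), Lc.T @ Xc)
    np.testing.assert_allclose(B, B_oracle, atol=1e-8)


def _tiny_lstm(rng, hidden=3, d=2):
    Y = rng.normal(size=(40, d))
    X = rng.normal(size=(40, 2))
    return fit_lstm(Y, X, np.repeat(np.arange(2), 20), {"hidden": hidden, "epochs": 1}, seed=0)


def test_lstm_zero_weights_give_bias_output(rng):
    model = _tiny_lstm(rng)
    for g in model.W_in:
        model.W_in[g][:] = 0
        model.W_rec[g][:] = 0
        model.b[g][:] = 0
    model.W_out[:] = 0
    model.b_out[:] = [1.5, -2.0]
    h, c, _ = lstm_step(model, np.zeros(2), np.zeros(3), np.zeros(3))
    np.testing.assert_array_equal(h, 0)
    pred = run_lstm(model, np.zeros((5, 2)), np.zeros(5, int))
    np.testing.assert_allclose(pred, np.tile([1.5, -2.0], (5, 1)))


def test_lstm_gates_match_scalar_brute_force(rng):
    """Vectorized gate arithmetic equals a pure-Python scalar evaluation of
    the forget/input/output/candidate equations to 1e-10."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    for trial in range(5):
        l, d = int(rng.integers(1, 4)), int(rng.integers(1, 4))
        model = _tiny_lstm(rng, hidden=l, d=d)
        y = rng.normal(size=(5, d))
        h = [0.0] * l
        c = [0.0] * l
        hv, cv = np.zeros(l), np.zeros(l)
        for t in range(5):
            gates = {}
            for g, fn in (("f", sig), ("i", sig), ("o", sig), ("c", math.tanh)):
                gates[g] = [
                    fn(
                        sum(y[t, a] * model.W_in[g][a, j] for a in range(d))
                        + sum(h[a] * model.W_rec[g][a, j] for a in range(l))
                        + model.b[g][j]
                    )
                    for j in range(l)
                ]
            c = [gates["f"][j] * c[j] + gates["i"][j] * gates["c"][j] for j in range(l)]
            h = [gates["o"][j] * math.tanh(c[j]) for j in range(l)]
            hv, cv, _ = lstm_step(model, y[t], hv, cv)
            np.testing.assert_allclose(hv, h, atol=1e-10)
            np.testing.assert_allclose(cv, c, atol=1e-10)


def test_lstm_deterministic_and_blockwise_permutation(rng):
    Y = rng.normal(size=(80, 3))
    X = rng.normal(size=(80, 2))
    trials = np.repeat(np.arange(4), 20)
    m1 = fit_lstm(Y, X, trials, {"hidden": 4, "epochs": 5}, seed=7)
    m2 = fit_lstm(Y, X, trials, {"hidden": 4, "epochs": 5}, seed=7)
    np.testing.assert_array_equal(m1.W_out, m2.W_out)
    pred = run_lstm(m1, Y, trials)
    np.testing.assert_array_equal(pred, run_lstm(m1, Y, trials))
    # permuting whole trials permutes outputs blockwise
    order = [2, 0, 3, 1]
    rows = np.concatenate([np.arange(20) + 20 * tr for tr in order])
    pred_perm = run_lstm(m1, Y[rows], np.repeat(np.arange(4), 20))
    np.testing.assert_allclose(pred_perm, pred[rows], atol=1e-12)


def test_lstm_is_causal(rng):
    Y = rng.normal(size=(60, 3))
    trials = np.zeros(60, int)
    model = _tiny_lstm(rng, hidden=4, d=3)
    base = run_lstm(model, Y, trials)
    Y2 = Y.copy()
    Y2[40:] += 50
    altered = run_lstm(model, Y2, trials)
    np.testing.assert_array_equal(base[:40], altered[:40])


def test_lstm_learns_noiseless_linear_map(rng):
    """Capacity check: on a noiseless linear map the trained network's test
    error is below 5% of the signal SD."""
    W = rng.normal(size=(4, 2))
    Y = rng.normal(size=(800, 4))
    X = Y @ W
    trials = np.repeat(np.arange(40), 20)
    model = fit_lstm(
        Y[:600], X[:600], trials[:600],
        {"hidden": 16, "epochs": 300, "eta": 3e-2, "minibatch": 30, "patience": 10**9, "rcov": 0.0},
        seed=0,
    )
    pred = run_lstm(model, Y[600:], trials[600:])
    rmse = np.sqrt(np.mean((pred - X[600:]) ** 2))
    assert rmse < 0.05 * X.std()


def test_lstm_input_validation(rng):
    model = _tiny_lstm(rng)
    with pytest.raises(ValueError):
        run_lstm(model, np.zeros((5, 9)), np.zeros(5, int))
    with pytest.raises(ValueError):
        fit_lstm(np.zeros((10, 2)), np.zeros((10, 2)), np.zeros(10, int), {"hidden": 0, "epochs": 1})
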
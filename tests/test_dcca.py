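import numpy as np
import pytest

from m1decode.benchmarks import nonlinear_two_view_data
from m1decode.cca import fit_lcca, total_correlation, transform_lcca
from m1decode.dcca import (
    DEFAULT_THETA,
    fit_dcca,
    invert_dcca_velocity,
    search_hyperparams,
    transform_dcca,
    validate_theta,
)
from m1decode.nets import MLP, pretrain_dae


def _linear_views(rng, n=2000, m=6):
    S = rng.normal(size=(n, 3))
    Z = S @ rng.normal(size=(3, m)) + 0.5 * rng.normal(size=(n, m))
    X = S + 0.3 * rng.normal(size=(n, 3))
    return Z, X


SMALL_THETA = dict(
    n_nodes_z=16,
    n_layers_z=1,
    n_nodes_x=16,
    n_layers_x=1,
    epochs=150,
    dae_epochs=3,
    batch_size=4096,
    eta=3e-3,
    lam=1e-3,
    l2=1e-5,
    rcov_z=1e-5,
    rcov_x=1e-5,
)


def test_dae_pretraining_reduces_reconstruction_loss(rng):
    data = rng.normal(size=(500, 10))
    _, _, losses = pretrain_dae(data, [10, 8], noise_frac=0.2, epochs=10, seed=0)
    for initial, final in losses:
        assert final < initial


def test_dae_seed_determinism(rng):
    data = rng.normal(size=(200, 6))
    W1, b1, _ = pretrain_dae(data, [6, 4], epochs=2, seed=3)
    W2, b2, _ = pretrain_dae(data, [6, 4], epochs=2, seed=3)
    np.testing.assert_array_equal(W1[0], W2[0])
    np.testing.assert_array_equal(b1[0], b2[0])


def test_mlp_identity_activation_is_linear(rng):
    net = MLP([4, 3, 2], activation="identity", seed=0)
    X = rng.normal(size=(10, 4))
    np.testing.assert_allclose(net(2 * X) + net(0 * X), 2 * net(X) + net(0 * X), atol=1e-12)


def test_linear_limit_matches_lcca(rng):
    """Identity activations, no reconstruction penalty: the deep model's
    total correlation equals linear CCA's."""
    Z, X = _linear_views(rng)
    lc = fit_lcca(Z, X)
    theta = dict(SMALL_THETA, activation="identity", lam=0.0, epochs=300, dae_epochs=0, eta=5e-3)
    dm = fit_dcca(Z, X, theta, seed=0)
    U, V = transform_dcca(dm, Z, X)
    assert total_correlation(U, V) == pytest.approx(float(lc.rho.sum()), abs=1e-3)


def test_objective_is_monitored_and_improves(rng):
    Z, X = _linear_views(rng, n=1000)
    dm = fit_dcca(Z, X, dict(SMALL_THETA, epochs=50), seed=1)
    assert len(dm.objective_curve) == 50
    assert dm.objective_curve[-1] >= dm.objective_curve[0]


def test_training_correlations_match_stored_rho(rng):
    Z, X = _linear_views(rng, n=1500)
    dm = fit_dcca(Z, X, dict(SMALL_THETA, epochs=60), seed=2)
    U, V = transform_dcca(dm, Z, X)
    from m1decode.cca import canonical_correlations

    np.testing.assert_allclose(canonical_correlations(U, V), dm.rho, atol=1e-6)


def test_transform_is_pointwise(rng):
    Z, X = _linear_views(rng, n=800)
    dm = fit_dcca(Z, X, dict(SMALL_THETA, epochs=30), seed=0)
    perm = rng.permutation(100)
    U1, _ = transform_dcca(dm, Z[:100][perm])
    U2, _ = transform_dcca(dm, Z[:100])
    np.testing.assert_array_equal(U1, U2[perm])
    # held-out correlations stay in [0, 1] up to sampling noise
    U, V = transform_dcca(dm, Z[500:], X[500:])
    from m1decode.cca import canonical_correlations

    rho = canonical_correlations(U, V)
    assert np.all(rho > -0.2) and np.all(rho <= 1.0)


def test_no_harm_on_linear_gaussian_data(rng):
    """Deep CCA gives up at most 0.02 total test correlation vs linear CCA
    in the purely linear regime."""
    Z, X = _linear_views(rng, n=4000)
    lc = fit_lcca(Z[:3000], X[:3000])
    Ul, Vl = transform_lcca(lc, Z[3000:], X[3000:])
    dm = fit_dcca(Z[:3000], X[:3000], dict(SMALL_THETA, epochs=250), seed=0)
    Ud, Vd = transform_dcca(dm, Z[3000:], X[3000:])
    assert total_correlation(Ud, Vd) >= total_correlation(Ul, Vl) - 0.02


def test_nonlinear_benchmark_advantage_small_scale():
    """On squashed-linear cross-view data the deep model recovers
    correlation the linear one cannot (reduced-n version)."""
    Z, X = nonlinear_two_view_data(n=6000, seed=3)
    lc = fit_lcca(Z[:4500], X[:4500])
    Ul, Vl = transform_lcca(lc, Z[4500:], X[4500:])
    theta = dict(
        n_nodes_z=32, n_layers_z=2, n_nodes_x=32, n_layers_x=2,
        epochs=300, dae_epochs=5, batch_size=4096, eta=2e-3,
        lam=1e-3, l2=1e-5, rcov_z=1e-4, rcov_x=1e-4,
    )
    dm = fit_dcca(Z[:4500], X[:4500], theta, seed=0)
    Ud, Vd = transform_dcca(dm, Z[4500:], X[4500:])
    assert total_correlation(Ud, Vd) >= total_correlation(Ul, Vl) + 0.05


def test_table_style_theta_accepted_and_strict_ranges():
    crt_like = {
        "n_nodes_z": 1024, "n_layers_z": 2, "rcov_z": 0.04,
        "n_nodes_x": 1024, "n_layers_x": 3, "rcov_x": 0.04,
        "batch_size": 256, "ae_batch_size": 256,
        "l2": 6.8e-4, "eta": 0.01, "lam": 0.01,
    }
    th = validate_theta(crt_like, strict=True)
    assert th["n_nodes_z"] == 1024 and th["n_layers_x"] == 3
    with pytest.raises(ValueError):
        validate_theta({"n_nodes_z": 2**12}, strict=True)
    with pytest.raises(ValueError):
        validate_theta({"bogus": 1})
    with pytest.raises(ValueError):
        validate_theta({"rcov_z": -0.1})


def test_identity_network_inversion_reduces_to_linear(rng):
    """An identity-activation model inverts through pseudo-inverses alone."""
    n = 1200
    X = rng.normal(size=(n, 3))
    Z = X @ rng.normal(size=(3, 6)) * 2
    theta = dict(SMALL_THETA, activation="identity", lam=0.0, epochs=250, dae_epochs=0, eta=5e-3)
    dm = fit_dcca(Z, X, theta, seed=0)
    U, V = transform_dcca(dm, Z, X)
    v_hat = invert_dcca_velocity(V, dm)  # exact canonical variables in
    np.testing.assert_allclose(v_hat, X[:, :2], atol=0.05)


def test_search_hyperparams_budget_and_determinism(rng):
    Z, X = _linear_views(rng, n=1200)
    space = {k: [v] for k, v in SMALL_THETA.items() if k not in ("epochs",)}
    theta1, log1 = search_hyperparams(Z, X, space, budget=1, seed=5, epochs=10)
    theta2, _ = search_hyperparams(Z, X, space, budget=1, seed=5, epochs=10)
    assert theta1 == theta2
    assert len(log1) == 1
    # single-point space returns that point
    for k, v in space.items():
        assert theta1[k] == v[0]
    with pytest.raises(ValueError):
        search_hyperparams(Z, X, {"eta": []}, budget=1)
    with pytest.raises(ValueError):
        search_hyperparams(Z, X, space, budget=0)


def test_search_reaches_lcca_optimum_on_linear_data(rng):
    Z, X = _linear_views(rng, n=2500)
    lc = fit_lcca(Z[:2000], X[:2000])
    Ul, Vl = transform_lcca(lc, Z[2000:], X[2000:])
    space = {
        "n_nodes_z": [16], "n_layers_z": [1], "n_nodes_x": [16], "n_layers_x": [1],
        "batch_size": [4096], "ae_batch_size": [256], "eta": [3e-3],
        "rcov_z": [1e-5], "rcov_x": [1e-5], "l2": [1e-5], "lam": [1e-3],
    }
    theta, _ = search_hyperparams(Z[:2000], X[:2000], space, budget=2, seed=0, epochs=150)
    dm = fit_dcca(Z[:2000], X[:2000], dict(theta, epochs=250), seed=0)
    Ud, Vd = transform_dcca(dm, Z[2000:], X[2000:])
    assert total_correlation(Ud, Vd) >= total_correlation(Ul, Vl) - 0.05
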
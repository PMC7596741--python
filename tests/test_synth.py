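import numpy as np
import pytest

from m1decode import preprocess, synth
from m1decode.session import write_session


def test_center_out_targets_evenly_spaced():
    _, hand_xy, trials = synth.generate_center_out_kinematics(200, n_targets=8, seed=0)
    # endpoint of the outward leg is the target
    n_leg = len(hand_xy) // (2 * len(trials))
    angles = set()
    for i in range(len(trials)):
        tgt = hand_xy[i * 2 * n_leg + n_leg - 1]
        angles.add(round(np.degrees(np.arctan2(tgt[1], tgt[0])) % 360))
    assert angles == {0, 45, 90, 135, 180, 225, 270, 315}


def test_min_jerk_peak_speed_matches_closed_form():
    reach_time, radius, dt = 0.6, 8.0, 0.002
    hand_t, hand_xy, _ = synth.generate_center_out_kinematics(
        5, reach_time_s=reach_time, radius_cm=radius, dt_s=dt, seed=1
    )
    speed = np.linalg.norm(np.gradient(hand_xy, dt, axis=0), axis=1)
    assert speed.max() == pytest.approx(1.875 * radius / reach_time, rel=0.02)


def test_velocity_zero_at_trial_boundaries():
    dt = 0.01
    hand_t, hand_xy, trials = synth.generate_center_out_kinematics(10, dt_s=dt, seed=2)
    n_per_trial = len(hand_xy) // len(trials)
    for i in range(len(trials)):
        seg = hand_xy[i * n_per_trial : (i + 1) * n_per_trial]
        # minimum-jerk legs start and end at rest
        assert np.linalg.norm(seg[1] - seg[0]) / dt < 0.05
        assert np.linalg.norm(seg[-1] - seg[-2]) / dt < 0.05


def test_sequential_within_workspace_and_deterministic():
    t1, xy1, tr1 = synth.generate_sequential_kinematics(50, workspace_cm=20.0, seed=5)
    t2, xy2, _ = synth.generate_sequential_kinematics(50, workspace_cm=20.0, seed=5)
    assert np.abs(xy1).max() <= 10.0 + 1e-9
    np.testing.assert_array_equal(xy1, xy2)
    # contiguous path: each trial starts where the previous one ended,
    # so every segment's displacement equals the spacing of its targets
    n_seg = len(xy1) // len(tr1)
    for i in range(len(tr1) - 1):
        end_prev = xy1[(i + 1) * n_seg - 1]
        start_next = xy1[(i + 1) * n_seg]
        assert np.linalg.norm(end_prev - start_next) < 1e-6
    assert np.all(np.diff(t1) > 0)


def test_constant_rate_unit_poisson_count():
    """b = 10 Hz, no tuning, 100 s: count within 3 sigma of 1000."""
    hand_t = np.arange(0, 100.0, 0.01)
    hand_xy = np.zeros((len(hand_t), 2))
    units, gt = synth.generate_tuned_population(
        hand_t,
        hand_xy,
        1,
        frac_nonlinear=0.0,
        rate_params={"baseline_hz": (10.0, 10.0), "depth_hz_per_cms": (0.0, 0.0), "speed_gain": (0.0, 0.0)},
        seed=0,
    )
    assert abs(len(units[0]) - 1000) < 3 * np.sqrt(1000)


def test_zero_rate_unit_is_silent():
    hand_t = np.arange(0, 10.0, 0.01)
    hand_xy = np.zeros((len(hand_t), 2))
    units, _ = synth.generate_tuned_population(
        hand_t,
        hand_xy,
        1,
        rate_params={"baseline_hz": (0.0, 0.0), "depth_hz_per_cms": (0.0, 0.0), "speed_gain": (0.0, 0.0)},
        seed=0,
    )
    assert len(units[0]) == 0


def test_poisson_dispersion_of_binned_counts():
    """Constant-rate units are Poisson: variance/mean of counts near 1."""
    hand_t = np.arange(0, 100.0, 0.01)
    hand_xy = np.zeros((len(hand_t), 2))
    units, _ = synth.generate_tuned_population(
        hand_t,
        hand_xy,
        4,
        rate_params={"baseline_hz": (20.0, 20.0), "depth_hz_per_cms": (0.0, 0.0), "speed_gain": (0.0, 0.0)},
        seed=3,
    )
    edges = np.arange(0, 100.0 + 1e-9, 0.05)
    assert len(edges) - 1 >= 2000
    for st in units:
        counts, _ = np.histogram(st, bins=edges)
        assert 0.8 <= counts.var() / counts.mean() <= 1.2


def test_preferred_direction_recovery_at_long_duration():
    """Linear tuned units: fitted tuning recovers phi within 10 degrees."""
    session, gt = synth.make_synthetic_session(
        {"n_units": 8, "n_trials": 420, "frac_nonlinear": 0.0}, seed=4
    )
    assert session.duration_s >= 500
    binned = preprocess.make_binned(session)
    for k in range(session.n_units):
        fit = preprocess.fit_linear_tuning(binned.Z[:, k], binned.X)
        err = np.angle(np.exp(1j * (fit.pref_direction_rad - gt.pref_direction_rad[k])))
        assert abs(np.degrees(err)) < 10


def test_ground_truth_regression_recovers_coefficients():
    """Empirical rates regressed on (vx, vy, speed) recover the generating
    coefficients within 15% at 500 s (on raw binned rates, no transform)."""
    # high baseline relative to modulation so the rate rectifier never binds
    # and the generating model is exactly linear
    session, gt = synth.make_synthetic_session(
        {
            "n_units": 5,
            "n_trials": 420,
            "frac_nonlinear": 0.0,
            "rate_params": {
                "baseline_hz": (20.0, 30.0),
                "depth_hz_per_cms": (0.2, 0.4),
                "speed_gain": (0.0, 0.1),
            },
        },
        seed=9,
    )
    counts, edges = preprocess.bin_spikes(session, 0.05)
    fr = counts / 0.05
    hand_xy = np.column_stack([session.hand_x, session.hand_y])
    X = preprocess.compute_kinematics(session.hand_t, hand_xy, edges)
    for k in range(session.n_units):
        fit = preprocess.fit_linear_tuning(fr[:, k], X)
        d_true = gt.depth_hz_per_cms[k]
        d_hat = np.hypot(*fit.beta1)
        assert d_hat == pytest.approx(d_true, rel=0.15)


@pytest.mark.parametrize(
    "config",
    [
        {"task": "center_out", "n_units": 155, "n_trials": 175},  # CRT-like
        {"task": "sequential", "n_units": 63, "n_trials": 496},  # SRT-like
    ],
)
def test_realistic_scale_sessions_validate(config):
    session, gt = synth.make_synthetic_session(config, seed=0)
    session.validate()
    assert session.n_units == config["n_units"]
    assert session.n_trials == config["n_trials"]
    assert gt.n_units == config["n_units"]


def test_seed_identical_sessions_write_identically(tmp_path):
    for name in ("a", "b"):
        session, _ = synth.make_synthetic_session({"n_units": 5, "n_trials": 5}, seed=11)
        write_session(session, tmp_path / f"{name}.h5")
    assert (tmp_path / "a.h5").read_bytes() == (tmp_path / "b.h5").read_bytes()


def test_bad_config_rejected():
    with pytest.raises(ValueError):
        synth.make_synthetic_session({"task": "jumping"}, seed=0)
    with pytest.raises(ValueError):
        synth.make_synthetic_session({"n_wrong": 1}, seed=0)
    with pytest.raises(ValueError):
        synth.generate_center_out_kinematics(5, dt_s=0.0)
    with pytest.raises(ValueError):
        synth.generate_tuned_population(np.arange(10.0), np.zeros((10, 2)), 0)
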
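"""Synthetic reaching sessions with known ground-truth velocity tuning.

Every downstream stage (preprocessing, representation learning, decoding)
is tested against sessions generated here, where the true tuning of each
unit is known.  Hand trajectories are minimum-jerk reaches — the standard
smooth-reach model with an analytic peak speed of ``1.875 * d / T`` for a
reach of distance ``d`` and duration ``T``.  Unit firing follows a
rectified cosine-tuning rate

    lambda(t) = max(0, b + d_mod * (vx cos(phi) + vy sin(phi)) + g * |v|)

optionally passed through a saturating squashing function (the "nonlinear"
units), and spikes are drawn from an inhomogeneous Poisson process by
thinning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .session import Session, Trial

__all__ = [
    "GroundTruth",
    "generate_center_out_kinematics",
    "generate_sequential_kinematics",
    "generate_tuned_population",
    "make_synthetic_session",
    "DEFAULT_RATE_PARAMS",
]

# Per-unit tuning parameter ranges (uniform draws).  Baselines and
# modulation depths sized so that, with ~25 cm/s peak reach speeds,
# tuned units modulate by roughly 10-30 Hz around a 5-15 Hz baseline —
# typical of well-isolated arm-area units.
DEFAULT_RATE_PARAMS = {
    "baseline_hz": (5.0, 15.0),
    "depth_hz_per_cms": (0.4, 1.2),
    "speed_gain": (0.0, 0.3),
}


@dataclass
class GroundTruth:
    """True tuning parameters recorded alongside a generated Session."""

    baseline_hz: np.ndarray
    pref_direction_rad: np.ndarray
    depth_hz_per_cms: np.ndarray
    speed_gain: np.ndarray
    nonlinear: np.ndarray  # bool per unit
    task: str = "center_out"
    noise_model: str = "poisson"
    extras: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.baseline_hz)


def _min_jerk_positions(p0, p1, duration_s, t):
    """Minimum-jerk path from p0 to p1 evaluated at times t in [0, T]."""
    tau = np.clip(t / duration_s, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return p0[None, :] + s[:, None] * (p1 - p0)[None, :]


def generate_center_out_kinematics(
    n_trials: int,
    n_targets: int = 8,
    reach_time_s: float = 0.6,
    radius_cm: float = 8.0,
    dt_s: float = 0.01,
    seed: int = 0,
):
    """Center-out task: out-and-back minimum-jerk reaches from home (0,0).

    Targets sit at equal angular spacing on a circle of ``radius_cm``
    (45 degrees apart for the canonical 8-target layout).  Each trial is
    one outward reach followed by the return, so hand velocity is zero at
    both trial boundaries.

    Returns (hand_t, hand_xy, trials) with trials tiling the session.
    """
    if n_targets < 2:
        raise ValueError("n_targets must be >= 2")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    rng = np.random.default_rng(seed)
    angles = 2 * np.pi * np.arange(n_targets) / n_targets
    trial_dur = 2 * reach_time_s
    n_leg = int(round(reach_time_s / dt_s))
    t_leg = np.arange(n_leg) * dt_s
    # leg spans (n_leg - 1) samples so its last sample lands exactly on the
    # target: trial boundaries then repeat the rest position (zero velocity)
    leg_dur = (n_leg - 1) * dt_s
    home = np.zeros(2)

    xy_parts, trials = [], []
    for i in range(n_trials):
        a = angles[rng.integers(n_targets)]
        target = radius_cm * np.array([np.cos(a), np.sin(a)])
        out = _min_jerk_positions(home, target, leg_dur, t_leg)
        back = _min_jerk_positions(target, home, leg_dur, t_leg)
        xy_parts.append(np.vstack([out, back]))
        trials.append(
            Trial(i * trial_dur, (i + 1) * trial_dur, f"t{int(round(a / (2 * np.pi / n_targets)))}")
        )
    hand_xy = np.vstack(xy_parts)
    hand_t = np.arange(len(hand_xy)) * dt_s
    return hand_t, hand_xy, trials


def generate_sequential_kinematics(
    n_trials: int,
    workspace_cm: float = 20.0,
    segment_time_s: float = 0.7,
    dt_s: float = 0.01,
    seed: int = 0,
):
    """Sequential task: minimum-jerk segments between random targets.

    Consecutive targets are drawn uniformly inside a square workspace of
    side ``workspace_cm`` centered on the origin; each trial is one
    segment starting where the previous one ended.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    rng = np.random.default_rng(seed)
    half = workspace_cm / 2.0
    n_seg = int(round(segment_time_s / dt_s))
    t_seg = np.arange(n_seg) * dt_s
    seg_dur = (n_seg - 1) * dt_s  # last sample lands exactly on the target

    pos = np.zeros(2)
    xy_parts, trials = [], []
    for i in range(n_trials):
        target = rng.uniform(-half, half, size=2)
        xy_parts.append(_min_jerk_positions(pos, target, seg_dur, t_seg))
        trials.append(Trial(i * segment_time_s, (i + 1) * segment_time_s, "sequence"))
        pos = target
    hand_xy = np.vstack(xy_parts)
    hand_t = np.arange(len(hand_xy)) * dt_s
    return hand_t, hand_xy, trials


def _hand_velocity(hand_t, hand_xy):
    dt = hand_t[1] - hand_t[0]
    v = np.gradient(hand_xy, dt, axis=0)
    return v


def _saturate(lam, lam_max):
    """Smooth saturating squash; linear near 0, asymptotes at lam_max."""
    return lam_max * np.tanh(lam / lam_max)


def generate_tuned_population(
    hand_t,
    hand_xy,
    n_units: int,
    frac_nonlinear: float = 0.5,
    rate_params: dict | None = None,
    frac_untuned: float = 0.0,
    seed: int = 0,
):
    """Draw cosine-tuned units and their inhomogeneous-Poisson spike trains.

    Rates follow the rectified cosine-tuning model on instantaneous hand
    velocity and speed.  A ``frac_nonlinear`` fraction of units squash the
    rate through a saturating nonlinearity before spiking (their relation
    to velocity is then no longer linear).  ``frac_untuned`` units fire at
    their baseline only.  Spiking uses per-sample thinning of a
    homogeneous Poisson process at the unit's peak rate.

    Returns (units, ground_truth) where units is a list of spike-time
    arrays.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rp = dict(DEFAULT_RATE_PARAMS)
    if rate_params:
        rp.update(rate_params)
    rng = np.random.default_rng(seed)
    duration = hand_t[-1] + (hand_t[1] - hand_t[0])

    v = _hand_velocity(hand_t, hand_xy)
    speed = np.linalg.norm(v, axis=1)

    b = rng.uniform(*rp["baseline_hz"], size=n_units)
    phi = rng.uniform(0, 2 * np.pi, size=n_units)
    d = rng.uniform(*rp["depth_hz_per_cms"], size=n_units)
    g = rng.uniform(*rp["speed_gain"], size=n_units)
    n_untuned = int(round(frac_untuned * n_units))
    if n_untuned:
        idx_untuned = rng.choice(n_units, size=n_untuned, replace=False)
        d[idx_untuned] = 0.0
        g[idx_untuned] = 0.0
    tuned_mask = (d > 0) | (g > 0)
    nonlinear = np.zeros(n_units, dtype=bool)
    tuned_idx = np.flatnonzero(tuned_mask)
    n_nl = int(round(frac_nonlinear * len(tuned_idx)))
    if n_nl:
        nonlinear[rng.choice(tuned_idx, size=n_nl, replace=False)] = True

    units = []
    for k in range(n_units):
        lam = np.maximum(
            0.0,
            b[k] + d[k] * (v[:, 0] * np.cos(phi[k]) + v[:, 1] * np.sin(phi[k])) + g[k] * speed,
        )
        if nonlinear[k]:
            # saturate at ~60% of the unit's dynamic peak: strong enough
            # that a linear read-out of the rate is visibly distorted
            lam_max = max(1e-6, 0.6 * (b[k] + lam.max()))
            lam = _saturate(lam, lam_max)
        units.append(_thinned_poisson(lam, hand_t, duration, rng))

    gt = GroundTruth(
        baseline_hz=b,
        pref_direction_rad=phi,
        depth_hz_per_cms=d,
        speed_gain=g,
        nonlinear=nonlinear,
    )
    return units, gt


def _thinned_poisson(lam, hand_t, duration, rng):
    """Inhomogeneous Poisson spike times via thinning (per-sample rates)."""
    lam_ub = float(lam.max())
    if lam_ub <= 0:
        return np.empty(0)
    n_cand = rng.poisson(lam_ub * duration)
    cand = np.sort(rng.uniform(0, duration, size=n_cand))
    # nearest-sample rate lookup
    idx = np.clip(np.searchsorted(hand_t, cand), 0, len(hand_t) - 1)
    keep = rng.uniform(0, lam_ub, size=n_cand) < lam[idx]
    return cand[keep]


DEFAULT_CONFIG = {
    "task": "center_out",  # or "sequential"
    "n_units": 60,
    "n_trials": 100,
    "n_targets": 8,
    "reach_time_s": 0.6,
    "radius_cm": 8.0,
    "segment_time_s": 0.7,
    "workspace_cm": 20.0,
    "dt_s": 0.01,
    "frac_nonlinear": 0.5,
    "frac_untuned": 0.0,
    "rate_params": None,
}


def make_synthetic_session(config: dict | None = None, seed: int = 0):
    """Generate a full Session (+ GroundTruth) from a config dict.

    Config keys (see DEFAULT_CONFIG): ``task`` is ``"center_out"`` or
    ``"sequential"``; population and kinematic parameters as documented
    on the generators.  One seed governs targets, tuning parameters and
    spikes; it is recorded in the session metadata.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)

    if cfg["task"] == "center_out":
        hand_t, hand_xy, trials = generate_center_out_kinematics(
            cfg["n_trials"],
            cfg["n_targets"],
            cfg["reach_time_s"],
            cfg["radius_cm"],
            cfg["dt_s"],
            seed=seed,
        )
    elif cfg["task"] == "sequential":
        hand_t, hand_xy, trials = generate_sequential_kinematics(
            cfg["n_trials"],
            cfg["workspace_cm"],
            cfg["segment_time_s"],
            cfg["dt_s"],
            seed=seed,
        )
    else:
        raise ValueError(f"unknown task {cfg['task']!r}")

    units, gt = generate_tuned_population(
        hand_t,
        hand_xy,
        cfg["n_units"],
        frac_nonlinear=cfg["frac_nonlinear"],
        rate_params=cfg["rate_params"],
        frac_untuned=cfg["frac_untuned"],
        seed=seed + 1,
    )
    gt.task = cfg["task"]
    duration = float(hand_t[-1] + cfg["dt_s"])
    session = Session(
        units=units,
        hand_t=hand_t,
        hand_x=hand_xy[:, 0],
        hand_y=hand_xy[:, 1],
        trials=trials,
        session_id=f"synthetic-{cfg['task']}-seed{seed}",
        duration_s=duration,
        meta={"seed": int(seed), "task": cfg["task"]},
    )
    session.validate()
    return session, gt
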
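"""Binning, square-root transform, Gaussian smoothing, kinematics, tuning.

The fixed preprocessing order is: bin spikes at 50 ms -> firing rates ->
square-root transform (variance stabilization for near-Poisson counts) ->
Gaussian kernel smoothing.  Hand position is averaged per bin and
differenced to velocity; speed is its Euclidean norm.  Unit inclusion is
gated by the r^2 of a linear tuning model on [vx, vy, speed] (the cosine
tuning model in velocity form).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import Session, TrialSplit

__all__ = [
    "BinnedData",
    "TuningFit",
    "bin_spikes",
    "sqrt_transform",
    "smooth_gaussian",
    "compute_kinematics",
    "fit_linear_tuning",
    "fit_tuning_table",
    "select_units",
    "make_binned",
    "EmptySelectionError",
]

DEFAULT_BIN_S = 0.05
DEFAULT_R2_THRESHOLD = 0.01


class EmptySelectionError(Exception):
    """No unit passed the tuning threshold."""


@dataclass
class BinnedData:
    """Aligned firing-rate and kinematic matrices on a common bin grid.

    Z : (n_bins, m) smoothed square-root firing rates
    X : (n_bins, 3) kinematics [vx, vy, speed] in cm/s
    t : bin centers (s); trial_of_bin : trial index per bin
    """

    t: np.ndarray
    Z: np.ndarray
    X: np.ndarray
    trial_of_bin: np.ndarray
    bin_s: float = DEFAULT_BIN_S

    def rows_for_trials(self, trial_ids) -> np.ndarray:
        return np.isin(self.trial_of_bin, np.asarray(trial_ids))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.Z, columns=[f"u{k}" for k in range(self.Z.shape[1])])
        df.insert(0, "t", self.t)
        df.insert(1, "trial", self.trial_of_bin)
        df[["vx", "vy", "speed"]] = self.X
        df.to_csv(path, index=False)


@dataclass
class TuningFit:
    """OLS fit of one unit's rate on [vx, vy, speed]."""

    beta0: float
    beta1: np.ndarray  # (2,) velocity coefficients
    beta2: float  # speed coefficient
    r2: float
    resid_var: float

    @property
    def pref_direction_rad(self) -> float:
        return float(np.arctan2(self.beta1[1], self.beta1[0]))


def bin_spikes(session: Session, bin_s: float = DEFAULT_BIN_S) -> tuple[np.ndarray, np.ndarray]:
    """Count spikes in non-overlapping bins.

    Returns (counts, bin_edges); counts[i, k] is the number of spikes of
    unit k in [edges[i], edges[i+1]).
    """
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n_bins = int(np.floor(session.duration_s / bin_s + 1e-9))
    if n_bins < 1:
        raise ValueError("bin_s longer than the session")
    edges = np.arange(n_bins + 1) * bin_s
    counts = np.empty((n_bins, session.n_units), dtype=np.int64)
    for k, st in enumerate(session.units):
        counts[:, k], _ = np.histogram(st, bins=edges)
    return counts, edges


def sqrt_transform(fr: np.ndarray) -> np.ndarray:
    """Elementwise square root (rejects negative rates)."""
    fr = np.asarray(fr, dtype=float)
    if np.any(fr < 0):
        raise ValueError("firing rates must be non-negative")
    return np.sqrt(fr)


def smooth_gaussian(fr: np.ndarray, sd_s: float, bin_s: float = DEFAULT_BIN_S) -> np.ndarray:
    """Per-column Gaussian kernel smoothing.

    The kernel (SD = sd_s / bin_s bins) is truncated at +/-4 SD and
    renormalized near the series edges so constants pass through
    unchanged.  sd_s == 0 is the identity.
    """
    if sd_s < 0:
        raise ValueError("sd_s must be >= 0")
    fr = np.atleast_2d(np.asarray(fr, dtype=float))
    sd_bins = sd_s / bin_s
    if sd_bins < 1e-6:  # kernel indistinguishable from a delta
        return fr.copy()
    half = int(np.ceil(4 * sd_bins))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sd_bins) ** 2)
    kernel /= kernel.sum()
    n = fr.shape[0]
    out = np.empty_like(fr)
    # edge renormalization: divide by in-window kernel mass
    norm = np.convolve(np.ones(n), kernel, mode="same")
    for k in range(fr.shape[1]):
        out[:, k] = np.convolve(fr[:, k], kernel, mode="same") / norm
    return out


def compute_kinematics(
    hand_t: np.ndarray,
    hand_xy: np.ndarray,
    edges: np.ndarray,
    trial_of_bin: np.ndarray | None = None,
) -> np.ndarray:
    """Bin-averaged position -> first-difference velocity -> speed.

    Velocity in bin i is (pos_i - pos_{i-1}) / bin_s; the first bin of
    each trial (and of the session) uses a forward difference instead so
    no cross-trial motion leaks in.  Returns (n_bins, 3) [vx, vy, speed].
    """
    hand_t = np.asarray(hand_t)
    n_bins = len(edges) - 1
    bin_s = edges[1] - edges[0]
    # floor-based assignment on the uniform grid (robust to float fuzz at edges)
    idx = np.clip(
        np.floor((hand_t - edges[0]) / bin_s + 1e-9).astype(np.int64), 0, n_bins - 1
    )
    inside = (hand_t >= edges[0] - 1e-12) & (hand_t < edges[-1] - 1e-12)
    counts = np.bincount(idx[inside], minlength=n_bins)
    if np.any(counts == 0):
        raise ValueError("gaps in hand data: a bin contains no hand samples")
    pos = np.empty((n_bins, 2))
    for a in range(2):
        pos[:, a] = np.bincount(idx[inside], weights=hand_xy[inside, a], minlength=n_bins) / counts

    v = np.empty_like(pos)
    v[1:] = np.diff(pos, axis=0) / bin_s
    v[0] = v[1] if n_bins > 1 else 0.0
    if trial_of_bin is not None:
        starts = np.flatnonzero(np.diff(trial_of_bin) != 0) + 1
        for s in starts:
            v[s] = v[s + 1] if s + 1 < n_bins and trial_of_bin[s + 1] == trial_of_bin[s] else 0.0
    speed = np.linalg.norm(v, axis=1)
    return np.column_stack([v, speed])


def fit_linear_tuning(z_k: np.ndarray, X: np.ndarray) -> TuningFit:
    """OLS of one unit's (smoothed, sqrt) rate on [vx, vy, speed]."""
    z_k = np.asarray(z_k, float)
    X = np.asarray(X, float)
    if len(z_k) < 10:
        raise ValueError("need at least 10 bins to fit tuning")
    sst = np.sum((z_k - z_k.mean()) ** 2)
    design = np.column_stack([np.ones(len(z_k)), X])
    beta, *_ = np.linalg.lstsq(design, z_k, rcond=None)
    resid = z_k - design @ beta
    ssr = np.sum(resid**2)
    r2 = 0.0 if sst <= 0 else max(0.0, 1.0 - ssr / sst)
    return TuningFit(
        beta0=float(beta[0]),
        beta1=beta[1:3].copy(),
        beta2=float(beta[3]),
        r2=float(min(1.0, r2)),
        resid_var=float(resid.var()),
    )


def fit_tuning_table(binned: BinnedData, trial_ids=None) -> list[TuningFit]:
    """Tuning fit for every unit, on the given (training) trials only."""
    rows = slice(None) if trial_ids is None else binned.rows_for_trials(trial_ids)
    Z, X = binned.Z[rows], binned.X[rows]
    return [fit_linear_tuning(Z[:, k], X) for k in range(Z.shape[1])]


def select_units(fits, threshold: float = DEFAULT_R2_THRESHOLD) -> list[int]:
    """Indices of units whose tuning r^2 exceeds the threshold."""
    if not fits:
        raise ValueError("no tuning fits supplied")
    kept = [k for k, f in enumerate(fits) if f.r2 > threshold]
    if not kept:
        raise EmptySelectionError(f"no unit exceeded r^2 > {threshold}")
    return kept


def make_binned(
    session: Session,
    bin_s: float = DEFAULT_BIN_S,
    smooth_sd_s: float = 0.08,
    drop_outside_trials: bool = True,
) -> BinnedData:
    """Full preprocessing pipeline: bin -> sqrt -> smooth + kinematics.

    Bins are assigned to the trial containing the bin center; bins outside
    any trial are dropped (successful-trial analysis).
    """
    counts, edges = bin_spikes(session, bin_s)
    centers = edges[:-1] + bin_s / 2
    trial_of_bin = np.full(len(centers), -1, dtype=np.int64)
    for i, tr in enumerate(session.trials):
        trial_of_bin[(centers >= tr.start_s) & (centers < tr.end_s)] = i

    fr = counts / bin_s
    Z = smooth_gaussian(sqrt_transform(fr), smooth_sd_s, bin_s)
    hand_xy = np.column_stack([session.hand_x, session.hand_y])
    X = compute_kinematics(session.hand_t, hand_xy, edges, trial_of_bin)

    if drop_outside_trials:
        keep = trial_of_bin >= 0
        centers, Z, X, trial_of_bin = centers[keep], Z[keep], X[keep], trial_of_bin[keep]
    return BinnedData(t=centers, Z=Z, X=X, trial_of_bin=trial_of_bin, bin_s=bin_s)
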
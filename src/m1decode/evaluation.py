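"""Decoding-quality metrics and method comparison statistics.

Per-trial decoding error is the mean Euclidean distance between true and
predicted velocity (or position) vectors within the trial.  Position is
reconstructed by cumulating decoded velocity from the trial's true start
position.  Method comparisons use the Friedman test across trials with
Bonferroni-corrected pairwise Wilcoxon post hocs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecodingResult",
    "tuning_r2",
    "decoding_error",
    "reconstruct_position",
    "correlation_metrics",
    "compare_methods",
    "training_error",
]


@dataclass
class DecodingResult:
    """Everything measured for one (representation, decoder) combination."""

    representation: str
    decoder: str
    true_v: np.ndarray
    pred_v: np.ndarray
    trial_of_bin: np.ndarray
    true_p: np.ndarray | None = None
    pred_p: np.ndarray | None = None
    velocity_error: np.ndarray | None = None  # per trial, cm/s
    position_error: np.ndarray | None = None  # per trial, cm
    corr: np.ndarray | None = None  # per-axis Pearson r
    extras: dict = field(default_factory=dict)


def tuning_r2(representation: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Velocity-tuning quality of each representation dimension.

    Per dimension, OLS on [vx, vy, speed]; returns the r^2 values
    (0 for constant dimensions).
    """
    R = np.atleast_2d(np.asarray(representation, float))
    if R.shape[0] == 1 and R.shape[1] != len(X):
        R = R.T
    design = np.column_stack([np.ones(len(X)), X])
    r2 = np.zeros(R.shape[1])
    for j in range(R.shape[1]):
        z = R[:, j]
        sst = np.sum((z - z.mean()) ** 2)
        if sst <= 0:
            continue
        beta, *_ = np.linalg.lstsq(design, z, rcond=None)
        ssr = np.sum((z - design @ beta) ** 2)
        r2[j] = np.clip(1 - ssr / sst, 0.0, 1.0)
    return r2


def decoding_error(true_v: np.ndarray, pred_v: np.ndarray, trial_of_bin) -> np.ndarray:
    """Per-trial mean Euclidean distance between true and predicted vectors."""
    true_v = np.asarray(true_v, float)
    pred_v = np.asarray(pred_v, float)
    if true_v.shape != pred_v.shape:
        raise ValueError("true and predicted series must have the same shape")
    trial_of_bin = np.asarray(trial_of_bin)
    dist = np.linalg.norm(true_v - pred_v, axis=1)
    errors = []
    for tr in np.unique(trial_of_bin):
        rows = trial_of_bin == tr
        if not rows.any():
            raise ValueError(f"trial {tr} has no bins")
        errors.append(dist[rows].mean())
    return np.asarray(errors)


def reconstruct_position(
    pred_v: np.ndarray,
    trial_of_bin,
    start_positions: dict,
    bin_s: float,
) -> np.ndarray:
    """Cumulate decoded velocity into position, restarting at each trial.

    ``start_positions`` maps trial index -> (x, y) at the trial onset,
    i.e. *before* the first bin's displacement:
    p(t_i) = p_start + sum_{k <= i} v_hat(t_k) * bin_s within the trial.
    """
    pred_v = np.asarray(pred_v, float)
    trial_of_bin = np.asarray(trial_of_bin)
    pos = np.empty_like(pred_v)
    for tr in np.unique(trial_of_bin):
        rows = np.flatnonzero(trial_of_bin == tr)
        if tr not in start_positions:
            raise KeyError(f"missing start position for trial {tr}")
        pos[rows] = np.asarray(start_positions[tr], float) + np.cumsum(
            pred_v[rows] * bin_s, axis=0
        )
    return pos


def correlation_metrics(true_v: np.ndarray, pred_v: np.ndarray, trial_of_bin=None):
    """Per-axis Pearson r over all bins; with trials, also per-trial mean/SD."""
    true_v = np.asarray(true_v, float)
    pred_v = np.asarray(pred_v, float)
    r = np.array(
        [stats.pearsonr(true_v[:, a], pred_v[:, a]).statistic for a in range(true_v.shape[1])]
    )
    if trial_of_bin is None:
        return r, None
    trial_of_bin = np.asarray(trial_of_bin)
    per_trial = []
    for tr in np.unique(trial_of_bin):
        rows = trial_of_bin == tr
        row_r = []
        for a in range(true_v.shape[2] if true_v.ndim == 3 else true_v.shape[1]):
            tv, pv = true_v[rows, a], pred_v[rows, a]
            if tv.std() > 0 and pv.std() > 0:
                row_r.append(stats.pearsonr(tv, pv).statistic)
            else:
                row_r.append(np.nan)
        per_trial.append(row_r)
    per_trial = np.asarray(per_trial)
    summary = pd.DataFrame(
        {
            "axis": ["x", "y"][: per_trial.shape[1]],
            "mean_r": np.nanmean(per_trial, axis=0),
            "sd_r": np.nanstd(per_trial, axis=0),
        }
    )
    return r, summary


def compare_methods(error_table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Friedman test across methods + Bonferroni-corrected post hocs.

    ``error_table``: one row per trial, one column per method, identical
    trial sets (aligned rows).  Returns the Friedman chi-square and p,
    and a pairwise table with Wilcoxon signed-rank and rank-sum
    statistics, Bonferroni-adjusted p-values, and a significance flag.
    """
    if error_table.isna().any().any():
        raise ValueError("mismatched trial sets: NaNs in the error table")
    methods = list(error_table.columns)
    if len(methods) < 2:
        raise ValueError("need at least two methods to compare")
    cols = [error_table[m].to_numpy() for m in methods]
    if len(methods) == 2:
        # Friedman needs >= 3 groups; with 2 it degenerates to a sign-like
        # test -> report the Wilcoxon signed-rank as the main test instead.
        if np.allclose(cols[0], cols[1]):
            chi2, p = 0.0, 1.0
        else:
            w = stats.wilcoxon(cols[0], cols[1])
            chi2, p = w.statistic, w.pvalue
        main_test = "wilcoxon"
    else:
        if all(np.allclose(cols[0], c) for c in cols[1:]):
            chi2, p = 0.0, 1.0  # no effect whatsoever
        else:
            chi2, p = stats.friedmanchisquare(*cols)
        main_test = "friedman"

    n_pairs = len(methods) * (len(methods) - 1) // 2
    rows = []
    for i in range(len(methods)):
        for j in range(i + 1, len(methods)):
            a, b = cols[i], cols[j]
            if np.allclose(a, b):
                w_stat, w_p = 0.0, 1.0
            else:
                w = stats.wilcoxon(a, b)
                w_stat, w_p = w.statistic, w.pvalue
            rs = stats.ranksums(a, b)
            p_adj = min(1.0, w_p * n_pairs)
            rows.append(
                {
                    "method_a": methods[i],
                    "method_b": methods[j],
                    "wilcoxon_stat": w_stat,
                    "ranksum_stat": rs.statistic,
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                    "better": methods[i] if np.median(a - b) < 0 else methods[j],
                }
            )
    return {
        "main_test": main_test,
        "chi2": float(chi2),
        "p": float(p),
        "posthoc": pd.DataFrame(rows),
    }


def training_error(true_v_train, pred_v_train) -> float:
    """Mean absolute (Euclidean) decoding error on the training set."""
    true_v_train = np.asarray(true_v_train, float)
    pred_v_train = np.asarray(pred_v_train, float)
    return float(np.mean(np.linalg.norm(true_v_train - pred_v_train, axis=1)))
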
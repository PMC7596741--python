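"""End-to-end orchestration: simulate -> preprocess -> represent -> decode -> evaluate.

One config drives the whole run.  A single global seed expands into
per-stage seeds through a stable hash so each stage is independently
reproducible; every artifact is listed in a manifest with its content
hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import cca, dcca, decoders, evaluation, latent, preprocess, synth
from .session import read_session, split_trials

__all__ = ["DEFAULT_CONFIG", "validate_config", "stage_seed", "run_pipeline"]

REPRESENTATIONS = ("efr", "pca", "fa", "lds", "lcca", "dcca")
DECODERS = ("lkf", "lstm")

DEFAULT_CONFIG = {
    "session": {"synthetic": dict(synth.DEFAULT_CONFIG)},
    "preprocess": {
        "bin_ms": 50,
        "smooth_sd_ms": 80,
        "r2_threshold": 0.01,
        "train_frac": 0.75,
    },
    "representations": list(REPRESENTATIONS),
    "representation_params": {
        "pca": {"q": None},  # None -> reconstruction-error selection
        "fa": {"q": None},
        "lds": {"q": None},
        "lcca": {"ridge": 1e-8},
        "dcca": {},  # theta overrides; see dcca.DEFAULT_THETA
    },
    "decoders": list(DECODERS),
    "lstm": {},  # theta overrides; see decoders.DEFAULT_LSTM_THETA
    "seed": 0,
    "strict": False,
}


def _merge(default, override):
    out = dict(default)
    for k, v in override.items():
        out[k] = _merge(default[k], v) if isinstance(v, dict) and isinstance(default.get(k), dict) else v
    return out


def validate_config(config: dict | None) -> dict:
    """Fill defaults and range-check a pipeline config."""
    config = config or {}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = _merge(DEFAULT_CONFIG, config)
    if "session" in config:  # the source is replaced, never merged with the default
        cfg["session"] = dict(config["session"])
    if cfg["preprocess"]["bin_ms"] <= 0:
        raise ValueError("bin_ms must be positive")
    if not 0 < cfg["preprocess"]["train_frac"] < 1:
        raise ValueError("train_frac must be in (0, 1)")
    bad = set(cfg["representations"]) - set(REPRESENTATIONS)
    if bad:
        raise ValueError(f"unknown representations: {sorted(bad)}")
    bad = set(cfg["decoders"]) - set(DECODERS)
    if bad:
        raise ValueError(f"unknown decoders: {sorted(bad)}")
    src = cfg["session"]
    if ("file" in src) == ("synthetic" in src):
        raise ValueError("session source must be exactly one of 'file' or 'synthetic'")
    if "file" in src and not Path(src["file"]).exists():
        raise ValueError(f"session file not found: {src['file']}")
    dcca.validate_theta(cfg["representation_params"].get("dcca") or {}, strict=cfg["strict"])
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed from the global seed via a stable hash (< 2^31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _extract(name, fitted, Z):
    if name == "efr":
        return Z
    if name in ("pca", "fa", "lds"):
        return latent.estimate_states(fitted, Z)
    if name == "lcca":
        return cca.transform_lcca(fitted, Z)[0]
    if name == "dcca":
        return dcca.transform_dcca(fitted, Z)[0]
    raise ValueError(name)


def run_pipeline(config: dict | None, outdir) -> dict:
    """Run the full benchmark grid and write a report bundle.

    Produces, under ``outdir``: the binned-data and tuning CSVs, canonical
    correlation table, per-combination prediction CSVs, per-trial error
    tables, the statistical comparison, and ``manifest.json`` with a
    content hash per artifact and the per-stage seeds.
    """
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {s: stage_seed(cfg["seed"], s) for s in ("simulate", "represent", "decode")}
    artifacts: dict[str, Path] = {}

    # --- session -----------------------------------------------------------
    if "file" in cfg["session"]:
        session = read_session(cfg["session"]["file"])
    else:
        session, _ = synth.make_synthetic_session(cfg["session"]["synthetic"], seed=seeds["simulate"])

    # --- preprocess --------------------------------------------------------
    pp = cfg["preprocess"]
    bin_s = pp["bin_ms"] / 1000.0
    binned = preprocess.make_binned(session, bin_s=bin_s, smooth_sd_s=pp["smooth_sd_ms"] / 1000.0)
    split = split_trials(session, pp["train_frac"])
    train_rows = binned.rows_for_trials(split.train_ids)
    test_rows = binned.rows_for_trials(split.test_ids)

    fits = preprocess.fit_tuning_table(binned, split.train_ids)
    kept = preprocess.select_units(fits, pp["r2_threshold"])
    binned.Z = binned.Z[:, kept]
    tuning_df = pd.DataFrame(
        {
            "unit": range(len(fits)),
            "r2": [f.r2 for f in fits],
            "pref_direction_rad": [f.pref_direction_rad for f in fits],
            "kept": [k in set(kept) for k in range(len(fits))],
        }
    )
    artifacts["tuning.csv"] = outdir / "tuning.csv"
    tuning_df.to_csv(artifacts["tuning.csv"], index=False)
    artifacts["binned.csv"] = outdir / "binned.csv"
    binned.to_csv(artifacts["binned.csv"])

    Z_tr, X_tr = binned.Z[train_rows], binned.X[train_rows]
    Z_te, X_te = binned.Z[test_rows], binned.X[test_rows]
    trials_tr = binned.trial_of_bin[train_rows]
    trials_te = binned.trial_of_bin[test_rows]

    # --- representations ---------------------------------------------------
    rp = cfg["representation_params"]
    models, rho_rows = {}, []
    for name in cfg["representations"]:
        if name == "efr":
            models[name] = None
        elif name in ("pca", "fa", "lds"):
            q = rp[name]["q"]
            if q is None:
                m = Z_tr.shape[1]
                cands = latent.pca_candidates(m) if name == "pca" else latent.fa_lds_candidates(m)
                q, _ = latent.select_dimensionality(name, Z_tr, Z_te, cands)
            if name == "pca":
                model = latent.fit_pca(Z_tr)
                model.q = q
            else:
                fitter = latent.fit_fa if name == "fa" else latent.fit_lds
                model = fitter(Z_tr, q)
            models[name] = model
        elif name == "lcca":
            models[name] = cca.fit_lcca(Z_tr, X_tr, ridge=rp["lcca"]["ridge"])
        elif name == "dcca":
            models[name] = dcca.fit_dcca(Z_tr, X_tr, rp["dcca"], seed=seeds["represent"])
        if name in ("lcca", "dcca"):
            mdl = models[name]
            if name == "lcca":
                U, V = cca.transform_lcca(mdl, Z_te, X_te)
            else:
                U, V = dcca.transform_dcca(mdl, Z_te, X_te)
            for k, r in enumerate(cca.canonical_correlations(U, V)):
                rho_rows.append({"method": name, "pair": k + 1, "rho_test": r})
    if rho_rows:
        artifacts["canonical_correlations.csv"] = outdir / "canonical_correlations.csv"
        pd.DataFrame(rho_rows).to_csv(artifacts["canonical_correlations.csv"], index=False)

    # --- decode + evaluate -------------------------------------------------
    hand_xy = np.column_stack([session.hand_x, session.hand_y])
    start_pos = {}
    for tr in np.unique(trials_te):
        i = int(np.searchsorted(session.hand_t, session.trials[tr].start_s))
        start_pos[tr] = hand_xy[min(i, len(hand_xy) - 1)]
    true_p = evaluation.reconstruct_position(X_te[:, :2], trials_te, start_pos, bin_s)

    results, error_rows = [], {}
    for name in cfg["representations"]:
        R_tr = _extract(name, models[name], Z_tr)
        R_te = _extract(name, models[name], Z_te)
        if name == "pca":  # principal components are re-smoothed before decoding
            R_tr = preprocess.smooth_gaussian(R_tr, pp["smooth_sd_ms"] / 1000.0, bin_s)
            R_te = preprocess.smooth_gaussian(R_te, pp["smooth_sd_ms"] / 1000.0, bin_s)
        for dec in cfg["decoders"]:
            if dec == "lkf":
                if name == "lds":  # latent dynamics decode through the NDF
                    ndf = decoders.fit_ndf(R_tr, X_tr)
                    pred = decoders.run_ndf(ndf, R_te)
                    dec_label = "ndf"
                else:
                    lkf = decoders.fit_lkf(X_tr, R_tr, trials_tr)
                    pred = decoders.run_lkf(lkf, R_te, trials_te)
                    dec_label = "lkf"
            else:
                lstm = decoders.fit_lstm(R_tr, X_tr, trials_tr, cfg["lstm"], seed=seeds["decode"])
                pred = decoders.run_lstm(lstm, R_te, trials_te)
                dec_label = "lstm"
            pred_p = evaluation.reconstruct_position(pred, trials_te, start_pos, bin_s)
            res = evaluation.DecodingResult(
                representation=name,
                decoder=dec_label,
                true_v=X_te[:, :2],
                pred_v=pred,
                trial_of_bin=trials_te,
                true_p=true_p,
                pred_p=pred_p,
                velocity_error=evaluation.decoding_error(X_te[:, :2], pred, trials_te),
                position_error=evaluation.decoding_error(true_p, pred_p, trials_te),
                corr=evaluation.correlation_metrics(X_te[:, :2], pred)[0],
            )
            results.append(res)
            error_rows[f"{name}+{dec_label}"] = res.velocity_error
            pred_df = pd.DataFrame(
                {"t": binned.t[test_rows], "trial": trials_te, "vx_hat": pred[:, 0], "vy_hat": pred[:, 1]}
            )
            key = f"predictions_{name}_{dec_label}.csv"
            artifacts[key] = outdir / key
            pred_df.to_csv(artifacts[key], index=False)

    error_df = pd.DataFrame(error_rows)
    artifacts["velocity_errors.csv"] = outdir / "velocity_errors.csv"
    error_df.to_csv(artifacts["velocity_errors.csv"], index=False)
    summary = pd.DataFrame(
        {
            "combo": error_df.columns,
            "mean_velocity_error": error_df.mean().to_numpy(),
            "sd_velocity_error": error_df.std().to_numpy(),
        }
    )
    artifacts["summary.csv"] = outdir / "summary.csv"
    summary.to_csv(artifacts["summary.csv"], index=False)

    comparison = None
    if error_df.shape[1] >= 2:
        comparison = evaluation.compare_methods(error_df)
        artifacts["comparison.csv"] = outdir / "comparison.csv"
        comparison["posthoc"].to_csv(artifacts["comparison.csv"], index=False)

    manifest = {
        "seed": cfg["seed"],
        "stage_seeds": seeds,
        "n_units_kept": len(kept),
        "n_trials": session.n_trials,
        "artifacts": {
            name: hashlib.sha256(path.read_bytes()).hexdigest() for name, path in artifacts.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "config": cfg,
        "results": results,
        "errors": error_df,
        "summary": summary,
        "comparison": comparison,
        "manifest": manifest,
    }
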
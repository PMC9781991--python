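"""Config-driven orchestration of the full selection/classification pipeline.

A pipeline run, configured by a nested mapping (usually loaded from YAML),
executes in order: synthetic database generation (or loading from disk),
band-pass filtering, whole-signal and windowed feature extraction, optional
ANOVA prescreen, wrapper selection (GA, PSO, or none) on the *unsegmented*
matrix, window-level SVM training and evaluation with the selected mask, and
the leave-one-feature-out sensitivity analysis.  Every artifact is a CSV or
JSON file in the output directory, and a manifest records the configuration
and a content hash for reproducibility.

Wrapper selection runs on whole-signal features rather than windows because
the windowed matrix is two orders of magnitude taller while (thanks to the
heavy overlap) its per-feature class distributions are close to the
whole-signal ones; the final classifier is still trained and validated on
windows.  Splits are stratified by movement class and keep all windows of a
repetition on one side, so overlapping windows can never leak between
training and validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import yaml

from . import synth
from .classify import SvmSpec, train_ova
from .errors import ParameterError
from .evaluate import evaluate, macro_average, sensitivity_analysis
from .features import (
    FeatureMatrix,
    PredictorSpec,
    default_predictors,
    extract_matrix,
    select_columns,
)
from .ga import GaConfig, run_ga
from .preprocess import FilterSpec, WindowSpec, bandpass, segment
from .prescreen import anova_prescreen, apply_prescreen
from .pso import PsoConfig, run_pso

log = logging.getLogger("emgselect")

DEFAULT_CONFIG: dict[str, Any] = {
    "database": {
        "n_subjects": 8,
        "movement_names": ["AP", "AT", "LP", "LT", "PD", "PI", "RR"],
        "n_reps": 20,
        "n_channels": 4,
        "fs": 1000.0,
        "duration": 7.0,
        "rest_lead": 1.0,
        "seed": 0,
        "rest_name": "RR",
    },
    "input": {"metadata": None},  # path to a metadata.csv to load instead of synthesizing
    "filter": {"low_hz": 10.0, "high_hz": 500.0, "order": 4},
    "window": {"length_ms": 250.0, "overlap_ms": 190.0},
    "trim": {"start_s": 1.0, "end_s": 1.97},
    "predictors": None,  # None -> all 26
    "prescreen": {"enabled": True, "alpha": 0.05},
    "selector": {
        "method": "ga",  # ga | pso | none
        "pop_size": 100,
        "mutation_rate": 0.02,
        "max_iterations": 100,
        "n_particles": 10,
        "w": 0.9,
        "c1": 2.0,
        "c2": 2.0,
        "target_error": None,
        "seed": 0,
    },
    "svm": {"kernel": "gaussian", "C": 1.0, "gamma": "scale", "standardize": True},
    "cv": {"k": 10, "seed": 0},
    "split": {
        "selection_fraction": 0.7,   # signal-level share used for wrapper selection
        "train_fraction": 0.25,      # window-level share used to train the final SVM
        "seed": 0,
    },
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge the defaults, an optional YAML file, and explicit overrides."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for layer in (_read_yaml(path) if path else None, overrides):
        if layer:
            _deep_update(cfg, layer)
    return cfg


def _read_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ParameterError(f"{path}: config must be a mapping")
    return loaded


def _deep_update(base: dict, new: dict) -> None:
    for key, value in new.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value


def grouped_split(
    m: FeatureMatrix, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean row masks (selected, held-out), stratified by movement and
    grouped by (subject, movement, repetition) so all windows of one
    repetition land on the same side."""
    if not 0 < fraction < 1:
        raise ParameterError("split fraction must be in (0, 1)")
    rows = m.rows
    groups = rows[["subject", "movement", "repetition"]].drop_duplicates()
    rng = np.random.default_rng(seed)
    chosen = []
    for movement, sub in groups.groupby("movement", sort=False):
        idx = sub.index.to_numpy()
        rng.shuffle(idx)
        n_take = max(1, int(round(fraction * idx.size)))
        if n_take >= idx.size:
            n_take = idx.size - 1
        chosen.append(idx[:n_take])
    chosen_groups = groups.loc[np.concatenate(chosen)]
    key_cols = ["subject", "movement", "repetition"]
    merged = rows[key_cols].merge(
        chosen_groups.assign(_in=True), on=key_cols, how="left"
    )
    in_mask = merged["_in"].notna().to_numpy()
    return in_mask, ~in_mask


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(cfg: dict, out_dir: str | Path) -> Path:
    """Execute the configured pipeline; returns the artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    # --- data -------------------------------------------------------------
    _stage("database")
    if cfg["input"].get("metadata"):
        recordings = synth.read_database(cfg["input"]["metadata"])
        class_order = sorted({r.movement for r in recordings})
    else:
        db = synth.DatabaseSpec(
            n_subjects=cfg["database"]["n_subjects"],
            movement_names=tuple(cfg["database"]["movement_names"]),
            n_reps=cfg["database"]["n_reps"],
            n_channels=cfg["database"]["n_channels"],
            fs=cfg["database"]["fs"],
            duration=cfg["database"]["duration"],
            rest_lead=cfg["database"]["rest_lead"],
            seed=cfg["database"]["seed"],
            rest_name=cfg["database"]["rest_name"],
        )
        recordings = synth.generate_database(db)
        class_order = list(db.movement_names)

    _stage("filter")
    fspec = FilterSpec(**cfg["filter"])
    recordings = [bandpass(r, fspec) for r in recordings]

    _stage("features")
    predictors = (
        default_predictors()
        if cfg["predictors"] is None
        else [PredictorSpec(n) for n in cfg["predictors"]]
    )
    wspec = WindowSpec(**cfg["window"])
    windowsets = [
        segment(r, wspec, cfg["trim"]["start_s"], cfg["trim"]["end_s"])
        for r in recordings
    ]
    signal_m = extract_matrix(recordings, predictors, class_order)
    window_m = extract_matrix(windowsets, predictors, class_order)
    signal_m.to_csv(out / "features_signals.csv")
    window_m.to_csv(out / "features_windows.csv")

    # --- prescreen --------------------------------------------------------
    if cfg["prescreen"]["enabled"]:
        _stage("prescreen")
        pres = anova_prescreen(signal_m, alpha=cfg["prescreen"]["alpha"])
        pres.to_csv(out / "prescreen.csv")
        signal_m = apply_prescreen(signal_m, pres)
        window_m = apply_prescreen(window_m, pres)

    # --- wrapper selection (on unsegmented signals) -----------------------
    svm = SvmSpec(**cfg["svm"])
    sel_mask_sig, _ = grouped_split(
        signal_m, cfg["split"]["selection_fraction"], cfg["split"]["seed"]
    )
    selection_m = signal_m.select_rows(sel_mask_sig)
    n_cols = signal_m.shape[1]
    method = cfg["selector"]["method"]
    if method == "ga":
        _stage("select (ga)")
        run = run_ga(
            selection_m,
            svm,
            GaConfig(
                n_genes=n_cols,
                pop_size=cfg["selector"]["pop_size"],
                mutation_rate=cfg["selector"]["mutation_rate"],
                max_iterations=cfg["selector"]["max_iterations"],
                target_error=cfg["selector"]["target_error"],
                seed=cfg["selector"]["seed"],
                cv_k=cfg["cv"]["k"],
                cv_seed=cfg["cv"]["seed"],
            ),
        )
    elif method == "pso":
        _stage("select (pso)")
        run = run_pso(
            selection_m,
            svm,
            PsoConfig(
                n_genes=n_cols,
                n_particles=cfg["selector"]["n_particles"],
                w=cfg["selector"]["w"],
                c1=cfg["selector"]["c1"],
                c2=cfg["selector"]["c2"],
                max_iterations=cfg["selector"]["max_iterations"],
                target_error=cfg["selector"]["target_error"],
                seed=cfg["selector"]["seed"],
                cv_k=cfg["cv"]["k"],
                cv_seed=cfg["cv"]["seed"],
            ),
        )
    elif method == "none":
        run = None
    else:
        raise ParameterError(f"unknown selector {method!r}")

    if run is not None:
        run.write_log(out / "selection_log.csv")
        run.write_mask(out / "best_mask.csv", signal_m.columns)
        mask = run.best_mask
    else:
        mask = np.ones(n_cols, dtype=np.int8)

    # --- window-level training and evaluation -----------------------------
    _stage("train/evaluate")
    masked_windows = select_columns(window_m, mask)
    train_rows, valid_rows = grouped_split(
        masked_windows, cfg["split"]["train_fraction"], cfg["split"]["seed"] + 1
    )
    w_train = masked_windows.select_rows(train_rows)
    w_valid = masked_windows.select_rows(valid_rows)
    model = train_ova(w_train, svm)
    joblib.dump(
        {"model": model, "mask": np.asarray(mask, dtype=int), "config": cfg},
        out / "model.joblib",
    )
    for split_name, matrix in (("training", w_train), ("validation", w_valid)):
        report = evaluate(model, matrix)
        report.to_csv(out / f"performance_{split_name}.csv")
        with open(out / f"performance_{split_name}_macro.json", "w") as fh:
            json.dump(macro_average(report), fh, indent=2)

    # --- sensitivity ------------------------------------------------------
    if int(np.asarray(mask).sum()) >= 2:
        _stage("sensitivity")
        full_train = window_m.select_rows(train_rows)
        full_valid = window_m.select_rows(valid_rows)
        sens = sensitivity_analysis(full_train, full_valid, mask, svm)
        sens.to_csv(out / "sensitivity.csv")

    manifest = {
        "config": cfg,
        "config_hash": _hash_config(cfg),
        "n_recordings": len(recordings),
        "signal_matrix_shape": list(signal_m.shape),
        "window_matrix_shape": list(window_m.shape),
        "n_selected": int(np.asarray(mask).sum()),
        "elapsed_s": round(time.perf_counter() - t0, 3),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
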
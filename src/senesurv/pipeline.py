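"""End-to-end orchestration: simulate/load -> quantify -> register ->
proximity -> cutpoints -> survival, with every intermediate table written
as plain CSV/JSON so each stage can be rerun or replaced independently.

Reruns with the same config and seed reproduce results.json byte for
byte; wall-clock timings only ever go to the run log.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .cutpoints import find_cutpoint_2tier, find_cutpoints_3tier, permutation_adjusted_p
from .proximity import patient_proximity
from .quantification import apply_positivity_threshold, classify_compartments, percent_positive
from .registration import map_section2_cells, register_cohort
from .survival_stats import km_estimate, logrank_test_labels
from .synthetic_data import simulate_cohort, _FLOAT_FORMAT

logger = logging.getLogger(__name__)

PROXIMITY_METRICS = ("mean_nn_dist_um", "pct_within_r")


class PipelineError(RuntimeError):
    """Raised with a stage-tagged message when any stage fails."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # re-raise with the failing stage named
                raise PipelineError(f"[{name}] {exc}") from exc
            return out, time.perf_counter() - t0
        return wrapper
    return deco


@_stage("simulate")
def _load_inputs(config: RunConfig):
    if config.sim is not None:
        cohort = simulate_cohort(config.sim)
        return cohort.cells, cohort.survival, cohort.landmarks, cohort.truth
    cells = pd.read_csv(config.cells_path)
    survival = pd.read_csv(config.survival_path)
    landmarks = pd.read_csv(config.landmarks_path) if config.landmarks_path else None
    return cells, survival, landmarks, None


@_stage("quantify")
def _quantify(config: RunConfig, cells: pd.DataFrame):
    markers = config.resolved_markers()
    if config.sim is not None:
        thr = config.sim.positivity_threshold
        for m in markers:
            cells = apply_positivity_threshold(cells, m, thr)
    if config.use_classifier:
        cells = classify_compartments(cells, train_frac=config.classifier_train_frac,
                                      seed=config.seed + 1)
    scores = pd.concat([percent_positive(cells, m) for m in markers], ignore_index=True)
    return cells, scores


@_stage("register")
def _register(cells: pd.DataFrame, landmarks):
    if landmarks is None or len(landmarks) == 0:
        return cells, pd.DataFrame(columns=["patient_id", "theta_deg", "tx_um",
                                            "ty_um", "scale", "rms_um"])
    transforms_table, transforms = register_cohort(landmarks)
    return map_section2_cells(cells, transforms), transforms_table


@_stage("proximity")
def _proximity(config: RunConfig, cells: pd.DataFrame):
    return patient_proximity(cells, r_um=config.r_um, direction=config.direction)


@_stage("cutpoints")
def _cutpoints(config: RunConfig, metric_scores: dict[str, pd.Series],
               survival: pd.DataFrame, excluded: list[str]):
    results: dict = {}
    tier_rows = []
    km_tables: dict[str, pd.DataFrame] = {}
    finders = {2: find_cutpoint_2tier, 3: find_cutpoints_3tier}
    perm_seed = config.seed * 1000 + 1
    for name in sorted(metric_scores):
        svals = metric_scores[name].dropna()
        results[name] = {}
        for endpoint in config.endpoints:
            surv_ep = survival[survival["endpoint"] == endpoint].set_index("patient_id")
            common = svals.index.intersection(surv_ep.index)
            dropped = set(surv_ep.index) - set(common)
            if dropped:
                excluded.append(f"{name}/{endpoint}: no score for patients {sorted(dropped)[:10]}")
            sc = svals.loc[common].to_numpy(dtype=float)
            dur = surv_ep.loc[common, "time_months"].to_numpy(dtype=float)
            ev = surv_ep.loc[common, "event"].to_numpy(dtype=int)
            results[name][endpoint] = {}
            for k in config.k_tiers:
                res = finders[k](sc, dur, ev, min_group_frac=config.min_group_frac,
                                 name=f"{name}/{endpoint}")
                res.p_adjusted = permutation_adjusted_p(
                    sc, dur, ev, k_tiers=k, B=config.n_permutations,
                    seed=perm_seed, min_group_frac=config.min_group_frac)
                perm_seed += 1
                results[name][endpoint][f"k{k}"] = res.to_dict()
                for pid, tier in zip(common, res.tiers):
                    tier_rows.append((pid, name, endpoint, k, tier))
                for tier in np.unique(res.tiers):
                    sel = res.tiers == tier
                    curve = km_estimate(dur[sel], ev[sel])
                    km_tables[f"{name}_{endpoint}_k{k}_{tier}"] = curve.to_frame()
                lr = logrank_test_labels(dur, ev, res.tiers)
                results[name][endpoint][f"k{k}"]["logrank_on_tiers"] = {
                    "chi2": lr.chi2, "df": lr.df, "p": lr.p}
    tiers = pd.DataFrame(tier_rows, columns=["patient_id", "metric", "endpoint", "k_tiers", "tier"])
    return results, tiers, km_tables


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write every artifact under ``out_dir``.

    Returns the results dictionary also written to ``results.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    excluded: list[str] = []

    (cells, survival, landmarks, truth), timings["simulate"] = _load_inputs(config)
    if config.sim is not None:
        cells.to_csv(out / "cells.csv", index=False, float_format=_FLOAT_FORMAT)
        survival.to_csv(out / "survival.csv", index=False, float_format=_FLOAT_FORMAT)
        if landmarks is not None:
            landmarks.to_csv(out / "landmarks.csv", index=False, float_format=_FLOAT_FORMAT)
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FORMAT)

    (cells, scores), timings["quantify"] = _quantify(config, cells)
    scores.to_csv(out / "scores.csv", index=False, float_format=_FLOAT_FORMAT)

    (cells, transforms_table), timings["register"] = _register(cells, landmarks)
    transforms_table.to_csv(out / "transforms.csv", index=False, float_format=_FLOAT_FORMAT)

    prox, timings["proximity"] = _proximity(config, cells)
    prox.to_csv(out / "proximity.csv", index=False, float_format=_FLOAT_FORMAT)
    n_prox_missing = int(prox["mean_nn_dist_um"].isna().sum())
    if n_prox_missing:
        excluded.append(f"proximity: {n_prox_missing} patient(s) without both populations")

    metric_scores: dict[str, pd.Series] = {}
    for m in config.resolved_markers():
        sub = scores[scores["marker"] == m].set_index("patient_id")["percent_positive"]
        metric_scores[m] = sub
    prox_idx = prox.set_index("patient_id")
    for metric in PROXIMITY_METRICS:
        metric_scores[metric] = prox_idx[metric]

    (cut_results, tiers, km_tables), timings["cutpoints"] = _cutpoints(
        config, metric_scores, survival, excluded)
    tiers.to_csv(out / "tiers.csv", index=False, float_format=_FLOAT_FORMAT)
    km_dir = out / "km"
    km_dir.mkdir(exist_ok=True)
    for name, table in km_tables.items():
        table.to_csv(km_dir / f"{name}.csv", index=False, float_format=_FLOAT_FORMAT)

    results = {
        "seed": config.seed,
        "n_patients": int(survival["patient_id"].nunique()),
        "endpoints": list(config.endpoints),
        "settings": {
            "r_um": config.r_um,
            "min_group_frac": config.min_group_frac,
            "n_permutations": config.n_permutations,
            "direction": config.direction,
            "k_tiers": list(config.k_tiers),
        },
        "cutpoints": cut_results,
    }
    with open(out / "cutpoints.json", "w") as fh:
        json.dump(cut_results, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out / "log.txt", "w") as fh:
        fh.write(f"senesurv {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        for stage, dt in timings.items():
            fh.write(f"stage {stage}: {dt:.2f} s\n")
        fh.write("excluded:\n")
        for line in excluded:
            fh.write(f"  - {line}\n")
    return results
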
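"""Cell-level quantification: compartment classification and marker scoring.

The per-patient readout is the percent of positive cells within classified
tumor epithelium, pooled across the patient's cores (pooling weights each
core by its evaluable cells; per-core averaging is available as an
option). Unclassified cells enter neither numerator nor denominator.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("mean_intensity", "local_density", "radial_dist_um")


def train_compartment_classifier(features, labels, seed: int = 0,
                                 n_estimators: int = 200) -> RandomForestClassifier:
    """Random-forest classifier separating tumor epithelium from stroma.

    Deterministic given ``seed``. Raises on a single-class training set or
    mismatched lengths.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must be matched (n, p) / (n,)")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("training set must contain at least 2 classes")
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return clf


def apply_positivity_threshold(cells: pd.DataFrame, marker: str, threshold: float) -> pd.DataFrame:
    """Set positive = (intensity >= threshold) for one marker; idempotent."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    if marker not in set(cells["marker"].unique()):
        raise KeyError(f"marker {marker!r} not present in cell table")
    out = cells.copy()
    sel = out["marker"] == marker
    out.loc[sel, "positive"] = (out.loc[sel, "intensity"] >= threshold).astype(int)
    return out


def percent_positive(cells: pd.DataFrame, marker: str,
                     compartment: str = "epithelium",
                     per_core: bool = False) -> pd.DataFrame:
    """Per-patient percent-positive score within the classified compartment.

    Pools cells across the patient's cores by default (the score is then
    the cell-count-weighted mean of per-core percentages); with
    ``per_core=True`` the unweighted mean of per-core percentages is
    returned instead. Patients without any evaluable cell are dropped with
    a logged warning.
    """
    sub = cells[(cells["marker"] == marker) & (cells["compartment"] == compartment)]
    all_patients = cells["patient_id"].unique()
    if per_core:
        core_pct = sub.groupby(["patient_id", "core_id"]).agg(
            pct=("positive", lambda v: 100.0 * np.mean(v)), n=("positive", "size"))
        grouped = core_pct.groupby("patient_id").agg(
            percent_positive=("pct", "mean"), n_cells_scored=("n", "sum"))
    else:
        grouped = sub.groupby("patient_id").agg(
            n_cells_scored=("positive", "size"), n_pos=("positive", "sum"))
        grouped["percent_positive"] = 100.0 * grouped["n_pos"] / grouped["n_cells_scored"]
        grouped = grouped.drop(columns="n_pos")
    missing = set(all_patients) - set(grouped.index)
    if missing:
        logger.warning("percent_positive(%s): %d patient(s) without %s cells excluded: %s",
                       marker, len(missing), compartment, sorted(missing)[:10])
    out = grouped.reset_index()
    out.insert(1, "marker", marker)
    return out[["patient_id", "marker", "percent_positive", "n_cells_scored"]].sort_values(
        "patient_id", ignore_index=True)


def extract_cell_features(cells: pd.DataFrame,
                          density_radius_um: float = 50.0) -> pd.DataFrame:
    """Per-cell feature vectors for compartment classification.

    One row per distinct section-1 cell with: mean stain intensity across
    the marker panel, local density (neighbors within ``density_radius_um``
    in the same core), and radial distance from the core center. Intended
    as a generic stand-in for the morphometric features a digital-pathology
    platform would export.
    """
    s1 = cells[cells["section_id"] == "S1"]
    per_cell = s1.groupby(["patient_id", "core_id", "cell_id"]).agg(
        x_um=("x_um", "first"), y_um=("y_um", "first"),
        compartment=("compartment", "first"),
        mean_intensity=("intensity", "mean")).reset_index()
    densities = np.empty(len(per_cell))
    pos = 0
    for _, grp in per_cell.groupby(["patient_id", "core_id"], sort=True):
        xy = grp[["x_um", "y_um"]].to_numpy()
        tree = cKDTree(xy)
        counts = np.array([len(c) - 1 for c in tree.query_ball_point(xy, density_radius_um)])
        densities[pos:pos + len(grp)] = counts
        pos += len(grp)
    per_cell["local_density"] = densities
    per_cell["radial_dist_um"] = np.hypot(per_cell["x_um"], per_cell["y_um"])
    return per_cell


def classify_compartments(cells: pd.DataFrame,
                          train_frac: float = 0.2,
                          seed: int = 0,
                          clf: Optional[RandomForestClassifier] = None) -> pd.DataFrame:
    """Replace section-1 compartment labels with classifier predictions.

    Trains on a stratified random fraction of the annotated cells (the
    stand-in for expert-marked regions) unless a fitted classifier is
    supplied, then predicts the compartment of every section-1 cell.
    """
    feats = extract_cell_features(cells)
    X = feats[list(FEATURE_NAMES)].to_numpy()
    y = feats["compartment"].to_numpy()
    if clf is None:
        rng = np.random.default_rng(seed)
        train_idx = []
        for label in np.unique(y):
            idx = np.nonzero(y == label)[0]
            k = max(int(round(train_frac * idx.size)), 1)
            train_idx.append(rng.choice(idx, size=k, replace=False))
        train_idx = np.concatenate(train_idx)
        clf = train_compartment_classifier(X[train_idx], y[train_idx], seed=seed)
    feats["predicted"] = clf.predict(X)
    key = ["patient_id", "core_id", "cell_id"]
    pred = feats.set_index(key)["predicted"]
    out = cells.copy()
    s1 = out["section_id"] == "S1"
    mapped = pd.MultiIndex.from_frame(out.loc[s1, key]).map(pred)
    out.loc[s1, "compartment"] = mapped.to_numpy()
    return out
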
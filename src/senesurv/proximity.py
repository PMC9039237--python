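"""Spatial proximity of CD8+ immune cells to p21+ senescent tumor cells.

Two patient-level statistics, computed after co-registration so both
populations live in the section-1 frame:

* mean nearest-neighbor distance between the populations (directional;
  default from each p21+ tumor cell to its closest CD8+ cell), and
* the percent of CD8+ cells with at least one p21+ cell within a radius
  (default 100 um, boundary inclusive).

Distances are center-to-center within a core; cross-core pairs are never
formed because cores are distinct tissue regions. No edge correction is
applied for cells near the core rim; an optional border margin can
exclude source cells within ``border_margin_um`` of the rim instead.
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


def _validate_points(pts, name: str) -> np.ndarray:
    a = np.asarray(pts, dtype=float)
    if a.size == 0:
        raise ValueError(f"{name} point set is empty")
    a = a.reshape(-1, 2)
    if not np.isfinite(a).all():
        raise ValueError(f"{name} points must be finite")
    return a


def nn_distances(source, target) -> np.ndarray:
    """Distance from every source point to its nearest target point."""
    s = _validate_points(source, "source")
    t = _validate_points(target, "target")
    dists, _ = cKDTree(t).query(s)
    return dists


def mean_nn_distance(source, target) -> float:
    """Mean over source cells of the distance to the nearest target cell (um)."""
    return float(nn_distances(source, target).mean())


def pct_within_radius(cd8, p21, r: float) -> float:
    """Percent of CD8+ cells with >= 1 p21+ cell within r um (closed ball)."""
    if r <= 0:
        raise ValueError("radius must be positive")
    d = nn_distances(cd8, p21)
    return float(100.0 * np.mean(d <= r))


def patient_proximity(cells: pd.DataFrame,
                      r_um: float = 100.0,
                      direction: str = "p21_to_cd8",
                      tumor_marker: str = "p21",
                      immune_marker: str = "CD8",
                      border_margin_um: float = 0.0,
                      core_radius_um: Optional[float] = 500.0) -> pd.DataFrame:
    """Per-patient proximity statistics pooled over cores.

    Expects a registered cell table (section-2 coordinates already mapped
    into the section-1 frame). The tumor population is restricted to
    marker-positive cells in classified epithelium; the immune population
    counts positive cells in all compartments. Cores missing either
    population contribute nothing; patients with no evaluable core get
    missing statistics and a logged warning (they drop out of downstream
    survival splits).
    """
    if direction not in ("p21_to_cd8", "cd8_to_p21"):
        raise ValueError("direction must be 'p21_to_cd8' or 'cd8_to_p21'")
    tumor = cells[(cells["marker"] == tumor_marker)
                  & (cells["positive"] == 1)
                  & (cells["compartment"] == "epithelium")]
    immune = cells[(cells["marker"] == immune_marker) & (cells["positive"] == 1)]
    t_cores = {k: g[["x_um", "y_um"]].to_numpy()
               for k, g in tumor.groupby(["patient_id", "core_id"], sort=True)}
    i_cores = {k: g[["x_um", "y_um"]].to_numpy()
               for k, g in immune.groupby(["patient_id", "core_id"], sort=True)}
    rows = []
    for pid in np.sort(cells["patient_id"].unique()):
        nn_all: list[np.ndarray] = []
        within = 0
        n_cd8 = 0
        n_src = 0
        n_tgt = 0
        cores = sorted({c for p, c in t_cores if p == pid} | {c for p, c in i_cores if p == pid})
        for core in cores:
            t_xy = t_cores.get((pid, core))
            i_xy = i_cores.get((pid, core))
            if t_xy is None or i_xy is None:
                continue
            src, tgt = (t_xy, i_xy) if direction == "p21_to_cd8" else (i_xy, t_xy)
            if border_margin_um > 0 and core_radius_um is not None:
                keep = np.hypot(src[:, 0], src[:, 1]) <= core_radius_um - border_margin_um
                src = src[keep]
                if len(src) == 0:
                    continue
            nn_all.append(nn_distances(src, tgt))
            n_src += len(src)
            n_tgt += len(tgt)
            within += int(np.sum(nn_distances(i_xy, t_xy) <= r_um))
            n_cd8 += len(i_xy)
        if n_cd8 == 0 or n_src == 0:
            logger.warning("patient %s has no core with both %s+ and %s+ cells; "
                           "proximity statistics missing", pid, tumor_marker, immune_marker)
            rows.append((pid, np.nan, np.nan, r_um, 0, 0, direction))
            continue
        mean_nn = float(np.concatenate(nn_all).mean())
        pct = float(100.0 * within / n_cd8)
        rows.append((pid, mean_nn, pct, r_um, n_src, n_tgt, direction))
    return pd.DataFrame(rows, columns=["patient_id", "mean_nn_dist_um", "pct_within_r",
                                       "r_um", "n_source", "n_target", "direction"])
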
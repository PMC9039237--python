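"""Synthetic TMA cohort generator.

Emulates the structure the downstream analysis assumes: per patient, three
1-mm cores with a central tumor-epithelium disc and a stromal rim; a
senescence-marker section (section S1) whose epithelial cells carry
Bernoulli positivity at a patient-latent percent per marker; a consecutive
CD8 section (S2) whose coordinates are the S1 frame pushed through a
patient-level rigid transform; and right-censored DSS/PFS survival whose
hazard is driven by the true tier of a driver marker (U-shaped: moderate
best) and by the latent CD8 attraction fraction q.

A fraction q of each core's CD8 cells is placed uniformly within the
attraction radius of a randomly chosen p21-positive epithelial cell
(radially clipped to the core); the remainder is uniform in the core disc.
The hazard uses the *latent* q so that recovery tests compare the
pipeline's realized spatial statistics against exactly known truth.

All randomness descends from a single seed; per-patient child streams are
spawned deterministically, and the survival/truth draws are separated from
the cell draws so survival tables are identical whether or not cells are
generated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ENDPOINTS, SimConfig
from .registration import RigidTransform2D

CELL_COLUMNS = [
    "patient_id", "core_id", "section_id", "cell_id",
    "x_um", "y_um", "compartment", "marker", "intensity", "positive",
]
SURVIVAL_COLUMNS = ["patient_id", "endpoint", "time_months", "event"]
LANDMARK_COLUMNS = ["patient_id", "core_id", "landmark_id", "x1_um", "y1_um", "x2_um", "y2_um"]

_FLOAT_FORMAT = "%.6g"


def tier_of(percent: float, boundaries: tuple[float, float]) -> str:
    """Map a percent-positive value to low / moderate / excessive."""
    lo, hi = boundaries
    if percent <= lo:
        return "low"
    if percent <= hi:
        return "moderate"
    return "excessive"


@dataclass
class SyntheticCohort:
    """Cell, survival, landmark and latent-truth tables for one simulated cohort."""

    cells: pd.DataFrame
    survival: pd.DataFrame
    landmarks: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False, float_format=_FLOAT_FORMAT)
        self.survival.to_csv(out / "survival.csv", index=False, float_format=_FLOAT_FORMAT)
        self.landmarks.to_csv(out / "landmarks.csv", index=False, float_format=_FLOAT_FORMAT)
        self.truth.to_csv(out / "truth.csv", index=False, float_format=_FLOAT_FORMAT)


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    r = radius * np.sqrt(rng.random(n))
    ang = rng.uniform(0.0, 2.0 * math.pi, n)
    return r * np.cos(ang), r * np.sin(ang)


def _intensities(rng: np.random.Generator, positive: np.ndarray, cfg: SimConfig) -> np.ndarray:
    n = positive.size
    pos_m, pos_s = cfg.positive_intensity
    neg_m, neg_s = cfg.negative_intensity
    vals = np.where(positive, rng.normal(pos_m, pos_s, n), rng.normal(neg_m, neg_s, n))
    return np.clip(vals, 0.0, None)


def simulate_cohort(config: SimConfig, include_cells: bool = True) -> SyntheticCohort:
    """Simulate a full cohort under the given configuration.

    With ``include_cells=False`` only the survival and truth tables are
    produced (cells/landmarks come back empty) — useful for survival-only
    calibration studies at large replicate counts.
    """
    config.validate()
    n_pat = config.n_patients
    radius = config.core_diameter_um / 2.0
    r_epi = radius * math.sqrt(config.epithelium_frac)
    hr = dict(zip(("low", "moderate", "excessive"), config.hazard_ratios))
    children = np.random.SeedSequence(config.seed).spawn(n_pat)

    surv_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    cell_parts: list[dict] = []
    lm_parts: list[dict] = []
    cell_counter = 0

    for i, ss in enumerate(children):
        pid = i + 1
        ss_latent, ss_cells = ss.spawn(2)
        rng = np.random.default_rng(ss_latent)

        percents: dict[str, float] = {}
        for m in config.marker_panel:
            mix = config.score_distribution[m]
            comp = rng.choice(len(mix.weights), p=np.asarray(mix.weights))
            percents[m] = float(np.clip(rng.normal(mix.means[comp], mix.sds[comp]), 0.5, 99.5))
        q = float(rng.beta(*config.proximity_attraction))
        tier = tier_of(percents[config.driver_marker],
                       config.tier_boundaries_true[config.driver_marker])
        lam = config.baseline_hazard * hr[tier] * math.exp(config.beta_proximity * (1.0 - q))
        for endpoint in ENDPOINTS:
            t_event = rng.exponential(1.0 / lam)
            t_cens = rng.uniform(0.0, config.censoring_window_months)
            surv_rows.append((pid, endpoint, min(t_event, t_cens), int(t_event <= t_cens)))
        if config.transform_fixed is not None:
            theta, tx, ty = config.transform_fixed
        else:
            theta = float(rng.uniform(*config.transform_theta_range_deg))
            tx, ty = (float(v) for v in rng.uniform(*config.transform_shift_range_um, size=2))
        truth_rows.append((pid, q, tier, theta, tx, ty, *[percents[m] for m in config.marker_panel]))

        if not include_cells:
            continue

        crng = np.random.default_rng(ss_cells)
        transform = RigidTransform2D(theta, tx, ty)
        for core in range(1, config.cores_per_patient + 1):
            n_cells = max(int(crng.poisson(config.cells_per_core)), 1)
            x, y = _uniform_disc(crng, n_cells, radius)
            is_epi = np.hypot(x, y) <= r_epi
            compartment = np.where(is_epi, "epithelium", "stroma")
            cell_ids = np.arange(cell_counter, cell_counter + n_cells)
            cell_counter += n_cells
            p21_anchor_xy = None
            for m in config.marker_panel:
                p_eff = np.where(is_epi, percents[m] / 100.0, config.stroma_background_rate)
                positive = crng.random(n_cells) < p_eff
                cell_parts.append({
                    "patient_id": np.full(n_cells, pid),
                    "core_id": np.full(n_cells, core),
                    "section_id": np.full(n_cells, "S1"),
                    "cell_id": cell_ids,
                    "x_um": x, "y_um": y,
                    "compartment": compartment,
                    "marker": np.full(n_cells, m),
                    "intensity": _intensities(crng, positive, config),
                    "positive": positive.astype(int),
                })
                if m == "p21":
                    sel = positive & is_epi
                    p21_anchor_xy = np.column_stack([x[sel], y[sel]])

            # CD8 cells on the consecutive section, generated in the S1 frame.
            n_cd8 = max(int(crng.poisson(config.cd8_per_core)), 1)
            n_att = 0
            if p21_anchor_xy is not None and len(p21_anchor_xy) > 0:
                n_att = int(crng.binomial(n_cd8, q))
            cx = np.empty(n_cd8)
            cy = np.empty(n_cd8)
            if n_att > 0:
                anchors = p21_anchor_xy[crng.integers(0, len(p21_anchor_xy), n_att)]
                ox, oy = _uniform_disc(crng, n_att, config.attraction_radius_um)
                ax, ay = anchors[:, 0] + ox, anchors[:, 1] + oy
                rr = np.hypot(ax, ay)
                clip = rr > radius  # radial clip back onto the core
                scale = np.where(clip, radius / np.maximum(rr, 1e-12), 1.0)
                cx[:n_att], cy[:n_att] = ax * scale, ay * scale
            ux, uy = _uniform_disc(crng, n_cd8 - n_att, radius)
            cx[n_att:], cy[n_att:] = ux, uy
            mapped = transform.apply(np.column_stack([cx, cy]))
            cd8_ids = np.arange(cell_counter, cell_counter + n_cd8)
            cell_counter += n_cd8
            cell_parts.append({
                "patient_id": np.full(n_cd8, pid),
                "core_id": np.full(n_cd8, core),
                "section_id": np.full(n_cd8, "S2"),
                "cell_id": cd8_ids,
                "x_um": mapped[:, 0], "y_um": mapped[:, 1],
                "compartment": np.full(n_cd8, "unclassified"),
                "marker": np.full(n_cd8, "CD8"),
                "intensity": _intensities(crng, np.ones(n_cd8, dtype=bool), config),
                "positive": np.ones(n_cd8, dtype=int),
            })

            # Fiducial landmarks on the core rim, jittered on section 2.
            k = config.landmarks_per_core
            ang0 = crng.uniform(0.0, 2.0 * math.pi)
            angles = ang0 + 2.0 * math.pi * np.arange(k) / k
            p1 = radius * np.column_stack([np.cos(angles), np.sin(angles)])
            p2 = transform.apply(p1) + crng.normal(0.0, config.landmark_noise_sd_um, (k, 2))
            lm_parts.append({
                "patient_id": np.full(k, pid),
                "core_id": np.full(k, core),
                "landmark_id": np.arange(k),
                "x1_um": p1[:, 0], "y1_um": p1[:, 1],
                "x2_um": p2[:, 0], "y2_um": p2[:, 1],
            })

    survival = pd.DataFrame(surv_rows, columns=SURVIVAL_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["patient_id", "q", "tier", "theta_deg", "tx_um", "ty_um",
                 *[f"percent_{m}" for m in config.marker_panel]],
    )
    if cell_parts:
        cells = pd.DataFrame({c: np.concatenate([p[c] for p in cell_parts]) for c in CELL_COLUMNS})
        landmarks = pd.DataFrame({c: np.concatenate([p[c] for p in lm_parts]) for c in LANDMARK_COLUMNS})
    else:
        cells = pd.DataFrame(columns=CELL_COLUMNS)
        landmarks = pd.DataFrame(columns=LANDMARK_COLUMNS)
    return SyntheticCohort(cells=cells, survival=survival, landmarks=landmarks,
                           truth=truth, config=config)
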
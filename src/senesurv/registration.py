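"""Rigid co-registration of consecutive TMA sections.

Cells stained on different serial sections live in different coordinate
frames. A per-patient rigid (optionally similarity) transform estimated
from matched fiducial landmarks — least-squares orthogonal Procrustes with
reflections disallowed (Kabsch) — maps them into one frame so distances
between populations on different sections are meaningful. An ICP loop is
available to refine a landmark-based initial guess against the full point
clouds.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class RigidTransform2D:
    """p' = s * R(theta) * p + (tx, ty), counterclockwise theta in degrees."""

    theta_deg: float
    tx: float
    ty: float
    scale: float = 1.0
    rms_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def rotation(self) -> np.ndarray:
        th = math.radians(self.theta_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ self.rotation().T + np.array([self.tx, self.ty])

    def inverse(self) -> "RigidTransform2D":
        Rinv = self.rotation().T
        t = -(1.0 / self.scale) * Rinv @ np.array([self.tx, self.ty])
        return RigidTransform2D(-self.theta_deg, t[0], t[1], 1.0 / self.scale)


def apply_transform(transform: RigidTransform2D, points: np.ndarray) -> np.ndarray:
    """Map an (n, 2) array of points through the transform."""
    return transform.apply(points)


def estimate_rigid_transform(
    landmarks_a: np.ndarray,
    landmarks_b: np.ndarray,
    allow_scale: bool = False,
) -> RigidTransform2D:
    """Least-squares transform mapping matched landmarks a onto b.

    Orthogonal Procrustes restricted to proper rotations (det +1): serial
    sections may rotate and shift on the slide but are never mirrored.
    The RMS residual after alignment is stored on the result.

    Raises
    ------
    ValueError
        Fewer than 2 matched pairs, mismatched shapes, non-finite input,
        or all source points coincident (rotation undefined).
    """
    a = np.asarray(landmarks_a, dtype=float)
    b = np.asarray(landmarks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("landmark sets must be matched (n, 2) arrays")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 matched landmark pairs")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("landmarks must be finite")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ac, bc = a - ca, b - cb
    var_a = float((ac**2).sum())
    if var_a < 1e-12:
        raise ValueError("all source landmarks coincide; rotation undefined")
    H = ac.T @ bc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, d])
    R = Vt.T @ D @ U.T
    s = float(np.trace(D @ np.diag(S)) / var_a) if allow_scale else 1.0
    if s <= 0:
        raise ValueError("degenerate similarity fit (non-positive scale)")
    t = cb - s * R @ ca
    theta = math.degrees(math.atan2(R[1, 0], R[0, 0]))
    resid = s * ac @ R.T + cb - b
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return RigidTransform2D(theta, float(t[0]), float(t[1]), s, rms_um=rms)


def icp_refine(
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    initial: RigidTransform2D,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> RigidTransform2D:
    """Iterative-closest-point refinement of an initial rigid transform.

    Alternates nearest-neighbor matching of mapped ``cells_a`` against
    ``cells_b`` with a Procrustes re-fit. The RMS residual is
    non-increasing by construction: if an update would raise it, the
    previous transform is returned (divergence guard).
    """
    a = np.asarray(cells_a, dtype=float)
    b = np.asarray(cells_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ICP needs nonempty point sets")
    tree = cKDTree(b)
    current = initial
    dists, idx = tree.query(current.apply(a))
    best_rms = float(np.sqrt((dists**2).mean()))
    for _ in range(max_iter):
        candidate = estimate_rigid_transform(a, b[idx])
        dists, new_idx = tree.query(candidate.apply(a))
        rms = float(np.sqrt((dists**2).mean()))
        if rms > best_rms:  # diverging: revert and stop
            break
        improved = best_rms - rms
        current, best_rms, idx = candidate, rms, new_idx
        if improved < tol:
            break
    return RigidTransform2D(current.theta_deg, current.tx, current.ty, current.scale, rms_um=best_rms)


def register_cohort(landmarks: pd.DataFrame, allow_scale: bool = False) -> tuple[pd.DataFrame, dict]:
    """Per-patient section-1 → section-2 transforms from fiducial landmarks.

    ``landmarks`` needs columns patient_id, x1_um, y1_um (section-1 frame)
    and x2_um, y2_um (section-2 frame); a patient's landmarks are pooled
    across cores since the whole section moves as one piece.

    Returns a transforms table (patient_id, theta_deg, tx_um, ty_um, scale,
    rms_um) and a dict patient_id -> RigidTransform2D.
    """
    out_rows = []
    transforms: dict = {}
    for pid, grp in landmarks.groupby("patient_id", sort=True):
        a = grp[["x1_um", "y1_um"]].to_numpy()
        b = grp[["x2_um", "y2_um"]].to_numpy()
        t = estimate_rigid_transform(a, b, allow_scale=allow_scale)
        transforms[pid] = t
        out_rows.append((pid, t.theta_deg, t.tx, t.ty, t.scale, t.rms_um))
    table = pd.DataFrame(out_rows, columns=["patient_id", "theta_deg", "tx_um", "ty_um", "scale", "rms_um"])
    return table, transforms


def map_section2_cells(cells: pd.DataFrame, transforms: dict) -> pd.DataFrame:
    """Map section-2 cell coordinates back into the section-1 frame.

    Uses the inverse of each patient's estimated section-1 → section-2
    transform. Section-1 rows are returned unchanged.
    """
    cells = cells.copy()
    s2 = cells[cells["section_id"] == "S2"]
    for pid, idx in s2.groupby("patient_id").groups.items():
        t = transforms.get(pid)
        if t is None:
            continue
        mapped = t.inverse().apply(cells.loc[idx, ["x_um", "y_um"]].to_numpy())
        cells.loc[idx, "x_um"] = mapped[:, 0]
        cells.loc[idx, "y_um"] = mapped[:, 1]
    return cells
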
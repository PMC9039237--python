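"""Configuration objects for simulation and pipeline runs.

`SimConfig` fully determines a synthetic cohort (same seed, same bytes);
`RunConfig` describes one end-to-end analysis run, sourced either from a
`SimConfig` block or from existing cell/survival/landmark tables.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

DEFAULT_MARKER_PANEL = ("NTAL", "ARMCX3", "p21", "EBP50", "gH2AX")

ENDPOINTS = ("DSS", "PFS")

TIER_NAMES_3 = ("low", "moderate", "excessive")
TIER_NAMES_2 = ("low", "high")


@dataclass(frozen=True)
class MixtureSpec:
    """Gaussian mixture on the [0, 100] percent-positive scale.

    Draws are clipped to (0.5, 99.5) so latent scores never degenerate to
    an exact 0% or 100% positivity.
    """

    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]

    def validate(self) -> None:
        if not (len(self.means) == len(self.sds) == len(self.weights)):
            raise ValueError("mixture components must have matching lengths")
        if not self.means:
            raise ValueError("mixture needs at least one component")
        if any(s <= 0 for s in self.sds):
            raise ValueError("mixture sds must be positive")
        if any(w < 0 for w in self.weights) or not math.isclose(sum(self.weights), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must be nonnegative and sum to 1")


# Wide tri-modal expression: markers whose positivity spreads over the whole
# percent scale, so that low/moderate/excessive tiers are all populated.
WIDE_MIXTURE = MixtureSpec((15.0, 50.0, 85.0), (10.0, 10.0, 10.0), (0.3, 0.4, 0.3))
# p21 marks scattered senescent cells: latent positivity stays low and tight,
# which keeps the baseline chance that a random CD8 cell falls within 100 um
# of some p21+ cell well below saturation (see docs/methods.md).
SPARSE_MIXTURE = MixtureSpec((8.0, 12.0, 17.0), (1.5, 2.0, 2.5), (0.3, 0.4, 0.3))


def _default_score_distribution(panel: Sequence[str]) -> dict[str, MixtureSpec]:
    return {m: (SPARSE_MIXTURE if m == "p21" else WIDE_MIXTURE) for m in panel}


def _default_tier_boundaries(panel: Sequence[str]) -> dict[str, tuple[float, float]]:
    # p21 boundaries sit at the terciles of its sparse mixture; all others at
    # the 30/70 boundaries of the wide mixture.
    return {m: ((10.0, 14.5) if m == "p21" else (30.0, 70.0)) for m in panel}


@dataclass
class SimConfig:
    """Parameters of the synthetic TMA cohort generator.

    Cohort shape follows the study design being emulated: up to 598
    patients, 3 cores of 1 mm diameter each, senescence markers on one
    section and CD8 on the consecutive co-registered section, with
    right-censored DSS/PFS endpoints.
    """

    n_patients: int = 598
    cores_per_patient: int = 3
    core_diameter_um: float = 1000.0
    cells_per_core: float = 200.0        # mean of the per-core Poisson cell count
    cd8_per_core: float = 80.0           # mean CD8+ count on the consecutive section
    epithelium_frac: float = 0.6         # area fraction of the central epithelial disc
    marker_panel: tuple[str, ...] = DEFAULT_MARKER_PANEL
    score_distribution: Optional[dict[str, MixtureSpec]] = None
    tier_boundaries_true: Optional[dict[str, tuple[float, float]]] = None
    driver_marker: str = "NTAL"          # marker whose true tier drives the hazard
    hazard_ratios: tuple[float, float, float] = (2.0, 1.0, 2.5)  # low, moderate, excessive
    proximity_attraction: tuple[float, float] = (2.0, 2.0)       # Beta(a, b) for q
    beta_proximity: float = 1.5          # log-hazard coefficient on (1 - q)
    baseline_hazard: float = 0.005       # events per month for the moderate tier
    censoring_window_months: float = 120.0
    attraction_radius_um: float = 100.0
    stroma_background_rate: float = 0.02
    positive_intensity: tuple[float, float] = (3.0, 0.5)   # mean, sd
    negative_intensity: tuple[float, float] = (1.0, 0.4)
    positivity_threshold: float = 2.0
    transform_theta_range_deg: tuple[float, float] = (-5.0, 5.0)
    transform_shift_range_um: tuple[float, float] = (-50.0, 50.0)
    transform_fixed: Optional[tuple[float, float, float]] = None  # (theta_deg, tx, ty)
    landmarks_per_core: int = 8
    landmark_noise_sd_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score_distribution is None:
            self.score_distribution = _default_score_distribution(self.marker_panel)
        if self.tier_boundaries_true is None:
            self.tier_boundaries_true = _default_tier_boundaries(self.marker_panel)
        self.marker_panel = tuple(self.marker_panel)
        self.validate()

    def validate(self) -> None:
        if self.n_patients <= 0 or self.cores_per_patient <= 0:
            raise ValueError("patient and core counts must be positive")
        if self.core_diameter_um <= 0:
            raise ValueError("core_diameter_um must be positive")
        if self.cells_per_core <= 0 or self.cd8_per_core <= 0:
            raise ValueError("mean cell counts must be positive")
        if not 0 < self.epithelium_frac < 1:
            raise ValueError("epithelium_frac must be in (0, 1)")
        if not self.marker_panel:
            raise ValueError("marker panel must not be empty")
        if self.driver_marker not in self.marker_panel:
            raise ValueError(f"driver marker {self.driver_marker!r} not in panel")
        if any(h <= 0 for h in self.hazard_ratios):
            raise ValueError("hazard ratios must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_window_months <= 0:
            raise ValueError("censoring window must be positive")
        if any(a <= 0 for a in self.proximity_attraction):
            raise ValueError("Beta attraction parameters must be positive")
        if self.attraction_radius_um <= 0:
            raise ValueError("attraction_radius_um must be positive")
        if self.landmarks_per_core < 2:
            raise ValueError("need at least 2 landmarks per core")
        if self.landmark_noise_sd_um < 0:
            raise ValueError("landmark noise sd must be nonnegative")
        for m in self.marker_panel:
            if m not in self.score_distribution:
                raise ValueError(f"no score distribution for marker {m!r}")
            self.score_distribution[m].validate()
            lo, hi = self.tier_boundaries_true[m]
            if not (0.0 < lo < hi < 100.0):
                raise ValueError(f"tier boundaries for {m!r} must be ordered within (0, 100)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["score_distribution"] = {
            m: {"means": list(mx.means), "sds": list(mx.sds), "weights": list(mx.weights)}
            for m, mx in self.score_distribution.items()
        }
        d["tier_boundaries_true"] = {m: list(v) for m, v in self.tier_boundaries_true.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "score_distribution" in d and d["score_distribution"] is not None:
            d["score_distribution"] = {
                m: MixtureSpec(tuple(v["means"]), tuple(v["sds"]), tuple(v["weights"]))
                for m, v in d["score_distribution"].items()
            }
        if "tier_boundaries_true" in d and d["tier_boundaries_true"] is not None:
            d["tier_boundaries_true"] = {m: tuple(v) for m, v in d["tier_boundaries_true"].items()}
        for key in ("marker_panel", "hazard_ratios", "proximity_attraction",
                    "positive_intensity", "negative_intensity",
                    "transform_theta_range_deg", "transform_shift_range_um"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("transform_fixed") is not None:
            d["transform_fixed"] = tuple(d["transform_fixed"])
        return cls(**d)


@dataclass
class RunConfig:
    """One end-to-end pipeline run.

    Exactly one of ``sim`` or the three input paths must be set.
    """

    sim: Optional[SimConfig] = None
    cells_path: Optional[str] = None
    survival_path: Optional[str] = None
    landmarks_path: Optional[str] = None
    markers: Optional[tuple[str, ...]] = None
    endpoints: tuple[str, ...] = ENDPOINTS
    r_um: float = 100.0
    min_group_frac: float = 0.10
    k_tiers: tuple[int, ...] = (2, 3)
    n_permutations: int = 199
    direction: str = "p21_to_cd8"
    use_classifier: bool = True
    classifier_train_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        self.endpoints = tuple(self.endpoints)
        self.k_tiers = tuple(self.k_tiers)
        if self.markers is not None:
            self.markers = tuple(self.markers)
        self.validate()

    def validate(self) -> None:
        has_paths = any(p is not None for p in (self.cells_path, self.survival_path, self.landmarks_path))
        if self.sim is not None and has_paths:
            raise ValueError("config must set either a sim block or input paths, not both")
        if self.sim is None:
            if self.cells_path is None or self.survival_path is None:
                raise ValueError("file-based runs need cells_path and survival_path")
        if not 0 < self.min_group_frac < 0.5:
            raise ValueError("min_group_frac must be in (0, 0.5)")
        if self.r_um <= 0:
            raise ValueError("r_um must be positive")
        if any(k not in (2, 3) for k in self.k_tiers):
            raise ValueError("k_tiers entries must be 2 or 3")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.direction not in ("p21_to_cd8", "cd8_to_p21"):
            raise ValueError("direction must be 'p21_to_cd8' or 'cd8_to_p21'")
        if not 0 < self.classifier_train_frac < 1:
            raise ValueError("classifier_train_frac must be in (0, 1)")

    def resolved_markers(self) -> tuple[str, ...]:
        if self.markers is not None:
            return self.markers
        if self.sim is not None:
            return self.sim.marker_panel
        raise ValueError("markers must be given explicitly for file-based runs")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict() if self.sim is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sim") is not None:
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("markers", "endpoints", "k_tiers"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
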
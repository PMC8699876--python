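"""Synthetic vessels and patient cohorts.

The vessel generator emulates a reconstructed stenosed coronary
segment: a tube of regular 72-point contours 0.5 mm apart, with
Gaussian-bump stenoses defined on *area* (a bump of severity s removes
the fraction s of the cross-sectional area at its throat, matching the
clinical "% area stenosis"), an outer wall offset by a constant
thickness, and optional gentle centerline curvature.

The cohort generator emulates a biohumoral/imaging feature table with a
plaque-progression outcome in which only age and baseline plaque burden
carry real (planted) effects; every other variable is null.  Marginals
are log-normal with physiologically plausible positive locations —
their exact shapes are irrelevant to the contracts being tested and are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import RecipeError
from .geometry import Contour, ContourStack, VesselModel
from .prognostic import (
    BIOHUMORAL_VARIABLES,
    IMAGING_VARIABLES,
    LIPIDOMIC_VARIABLES,
    CohortTable,
)

__all__ = [
    "StenosisSpec",
    "VesselRecipe",
    "CohortRecipe",
    "generate_vessel",
    "generate_cohort",
    "child_seeds",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """Fan a global seed out into n independent child seeds (< 2**31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class StenosisSpec:
    """A single lesion: axial center (mm), length (mm) and the fraction
    of cross-sectional area lost at the throat."""

    center: float
    length: float
    severity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity < 1.0):
            raise RecipeError(f"severity must be in [0, 1), got {self.severity}")
        if self.length <= 0:
            raise RecipeError("stenosis length must be positive")


@dataclass(frozen=True)
class VesselRecipe:
    length: float = 30.0  # mm
    base_radius: float = 1.5  # mm lumen radius away from lesions
    wall_thickness: float = 0.5  # mm outer-wall offset
    stenoses: tuple[StenosisSpec, ...] = ()
    curvature: float = 0.0  # 1/mm; 0 = straight
    points_per_contour: int = 72
    spacing: float = 0.5  # mm
    radius_noise: float = 0.0  # mm of per-station jitter (0 = none)
    seed: int = 0
    case_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.base_radius <= 0 or self.wall_thickness <= 0:
            raise RecipeError("base_radius and wall_thickness must be positive")
        if self.points_per_contour < 3:
            raise RecipeError("need at least 3 points per contour")
        if self.spacing <= 0 or self.length < 2 * self.spacing:
            raise RecipeError("length must cover at least two stations")
        object.__setattr__(self, "stenoses", tuple(self.stenoses))


def _area_factor(z: np.ndarray, stenoses: Sequence[StenosisSpec]) -> np.ndarray:
    factor = np.ones_like(z)
    for s in stenoses:
        width = s.length / 4.0  # Gaussian sigma: lesion spans ~ ±2 sigma
        factor = factor - s.severity * np.exp(-0.5 * ((z - s.center) / width) ** 2)
    return factor


def _frames(z: np.ndarray, curvature: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centerline points and in-plane basis vectors (u, v) per station.

    For curvature k > 0 the centerline is a circular arc of radius 1/k
    in the x-z plane, parameterised by arclength; contours sit in the
    plane normal to the tangent.
    """
    if curvature == 0.0:
        centers = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        u = np.tile([1.0, 0.0, 0.0], (len(z), 1))
        v = np.tile([0.0, 1.0, 0.0], (len(z), 1))
        return centers, u, v
    radius = 1.0 / curvature
    phi = z / radius
    centers = np.column_stack(
        [radius * (1.0 - np.cos(phi)), np.zeros_like(z), radius * np.sin(phi)]
    )
    tangent = np.column_stack([np.sin(phi), np.zeros_like(phi), np.cos(phi)])
    v = np.tile([0.0, 1.0, 0.0], (len(z), 1))
    u = np.cross(v, tangent)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    return centers, u, v


def generate_vessel(recipe: VesselRecipe) -> VesselModel:
    """Deterministic stenosed tube per the recipe (bit-identical per seed)."""
    n_stations = int(round(recipe.length / recipe.spacing)) + 1
    z = np.arange(n_stations) * recipe.spacing
    factor = _area_factor(z, recipe.stenoses)
    if np.any(factor <= 0):
        raise RecipeError("overlapping stenoses drive the lumen area to zero")
    base_area = np.pi * recipe.base_radius**2
    lumen_r = np.sqrt(factor * base_area / np.pi)
    if recipe.radius_noise > 0:
        rng = np.random.default_rng(recipe.seed)
        lumen_r = lumen_r + rng.normal(0.0, recipe.radius_noise, size=n_stations)
        if np.any(lumen_r <= 0):
            raise RecipeError("radius noise drove the lumen radius negative")
    outer_r = lumen_r + recipe.wall_thickness

    # regular polygons: enclosed area of an m-gon of circumradius R is
    # (m/2) R^2 sin(2 pi/m); use the circumradius that reproduces the
    # target area exactly so 'severity' is exact on areas.
    m = recipe.points_per_contour
    poly_factor = 0.5 * m * np.sin(2.0 * np.pi / m)
    theta = 2.0 * np.pi * np.arange(m) / m
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    centers, u, v = _frames(z, recipe.curvature)

    def ring(center: np.ndarray, uu: np.ndarray, vv: np.ndarray, r_eff: float) -> Contour:
        circumradius = np.sqrt(np.pi * r_eff**2 / poly_factor)
        pts = (
            center
            + circumradius * cos_t[:, None] * uu
            + circumradius * sin_t[:, None] * vv
        )
        return Contour(pts)

    lumen = ContourStack(
        tuple(ring(centers[i], u[i], v[i], lumen_r[i]) for i in range(n_stations)),
        spacing=recipe.spacing,
    )
    wall = ContourStack(
        tuple(ring(centers[i], u[i], v[i], outer_r[i]) for i in range(n_stations)),
        spacing=recipe.spacing,
    )
    return VesselModel(case_id=recipe.case_id, lumen=lumen, outer_wall=wall)


#: Log-normal location/shape (median, sigma of log) per cohort variable,
#: in conventional clinical units.  Exact marginals are a convenience,
#: not a tested contract.
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "alanine": (25.0, 0.4),
    "alkaline": (70.0, 0.3),
    "aspartate": (25.0, 0.35),
    "gamma_gt": (30.0, 0.5),
    "creatinine": (0.9, 0.2),
    "uric_acid": (5.5, 0.25),
    "glucose": (95.0, 0.2),
    "triglycerides": (130.0, 0.4),
    "cholesterol": (190.0, 0.2),
    "ldl": (115.0, 0.25),
    "hdl": (50.0, 0.25),
    "reactive_protein": (2.0, 0.8),
    "interleukin_6": (2.0, 0.7),
    "leptin": (10.0, 0.6),
    "icam1": (250.0, 0.3),
    "vcam1": (600.0, 0.3),
    "ce_18_3": (1.0, 0.4),
    "ce_20_3": (1.5, 0.4),
    "ce_20_4": (5.0, 0.4),
    "ps_38_6": (0.2, 0.4),
    "min_ess": (0.6, 0.4),
    "max_ldl_concentration": (5e-4, 0.3),
}


@dataclass(frozen=True)
class CohortRecipe:
    """Cohort with planted age and baseline-plaque-burden effects.

    Coefficients are on centred predictors (age − 60 years, burden −
    40%), so the outcome is centred progression.  All biohumoral,
    lipidomic and other imaging variables are null by construction.
    """

    n_patients: int = 200
    coef_age: float = 0.01  # outcome units per year
    coef_burden: float = -0.011  # outcome units per % burden
    noise_sd: float = 0.15
    outcome_kind: str = "continuous"
    marginals: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise RecipeError("need at least 10 patients")
        if self.noise_sd < 0:
            raise RecipeError("noise_sd must be non-negative")
        if self.outcome_kind not in ("continuous", "binary"):
            raise RecipeError(f"unknown outcome kind {self.outcome_kind!r}")


def generate_cohort(recipe: CohortRecipe) -> CohortTable:
    """Deterministic synthetic cohort per the recipe."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_patients
    data: dict[str, np.ndarray] = {}
    data["age"] = np.clip(rng.normal(60.0, 9.0, n), 35.0, 85.0)
    data["baseline_plaque_burden"] = np.clip(rng.normal(40.0, 12.0, n), 5.0, 80.0)
    for name, (median, sigma) in recipe.marginals.items():
        data[name] = np.exp(rng.normal(np.log(median), sigma, n))
    data["smartffr"] = np.clip(rng.normal(0.93, 0.04, n), 0.6, 1.0)

    linpred = recipe.coef_age * (data["age"] - 60.0) + recipe.coef_burden * (
        data["baseline_plaque_burden"] - 40.0
    )
    if recipe.outcome_kind == "continuous":
        outcome = linpred + rng.normal(0.0, recipe.noise_sd, n)
    else:
        scale = recipe.noise_sd if recipe.noise_sd > 0 else 1.0
        prob = 1.0 / (1.0 + np.exp(-linpred / scale))
        outcome = (rng.uniform(size=n) < prob).astype(float)
    data["plaque_progression"] = outcome

    columns = (
        ["age"]
        + list(BIOHUMORAL_VARIABLES)
        + list(LIPIDOMIC_VARIABLES)
        + list(IMAGING_VARIABLES)
        + ["plaque_progression"]
    )
    df = pd.DataFrame(data)[columns]
    return CohortTable(
        data=df,
        biohumoral_columns=BIOHUMORAL_VARIABLES,
        outcome_column="plaque_progression",
        outcome_kind=recipe.outcome_kind,  # type: ignore[arg-type]
    )
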
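"""Contour-stack vessel geometry and the area-perturbation procedure.

A reconstructed coronary segment is represented as two stacks of closed
planar contours (lumen and outer wall), each contour an ordered ring of
points (72 by convention) lying 0.5 mm apart along the centerline.  The
perturbation procedure emulates a systematic segmentation error: every
contour is scaled isotropically in its own plane about its centroid so
that its enclosed area changes by a prescribed fraction (e.g. ±5%), then
translated back so the centroid is preserved.

Coordinates are millimetres throughout; areas are mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import GeometryError, InvalidContourError, LoftError

__all__ = [
    "Contour",
    "ContourStack",
    "VesselModel",
    "SurfaceMesh",
    "contour_centroid",
    "contour_area",
    "scale_contour",
    "perturb_vessel",
    "make_error_models",
    "loft_surface",
]

PerturbationTag = Literal["original", "overestimated", "underestimated"]


def _plane_basis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best-fit plane of a point ring: (unit normal, in-plane u, in-plane v).

    The normal is the right singular vector with the smallest singular
    value of the centred point cloud; u, v span the plane.
    """
    centred = points - points.mean(axis=0)
    # SVD of an (n, 3) cloud: rows of Vt are principal directions.
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    u, v, normal = vt[0], vt[1], vt[2]
    if normal[2] < 0:  # orient consistently when possible
        normal = -normal
    return normal, u, v


@dataclass(frozen=True)
class Contour:
    """Ordered closed ring of 3-D points (the ring is implicitly closed)."""

    points: np.ndarray  # shape (n, 3), mm

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidContourError(f"points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 3:
            raise InvalidContourError(
                f"a contour needs at least 3 points, got {pts.shape[0]}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidContourError("contour contains non-finite coordinates")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def centroid(self) -> np.ndarray:
        """Vertex centroid (arithmetic mean of the ring vertices), mm."""
        return self.points.mean(axis=0)

    @property
    def plane_normal(self) -> np.ndarray:
        return _plane_basis(self.points)[0]

    def projected_2d(self) -> np.ndarray:
        """Ring projected onto its best-fit plane, as (n, 2) in-plane coords."""
        _, u, v = _plane_basis(self.points)
        centred = self.points - self.centroid
        return np.column_stack([centred @ u, centred @ v])

    @property
    def area(self) -> float:
        return contour_area(self)

    def is_simple(self) -> bool:
        """True if the projected ring does not self-intersect."""
        from shapely.geometry import Polygon

        return Polygon(self.projected_2d()).is_simple


def contour_centroid(contour: Contour) -> np.ndarray:
    """Vertex centroid of a contour (mean of its ring vertices), mm."""
    return contour.centroid


def contour_area(contour: Contour) -> float:
    """Enclosed area of the ring projected on its best-fit plane (shoelace), mm².

    Raises
    ------
    InvalidContourError
        If the ring is degenerate (collinear points, zero enclosed area).
    """
    xy = contour.projected_2d()
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0.0 or not np.isfinite(area):
        raise InvalidContourError("degenerate contour: zero enclosed area")
    return float(area)


def scale_contour(contour: Contour, area_factor: float) -> Contour:
    """Scale a contour in its own plane so its area changes by ``area_factor``.

    Every vertex is moved along the ray from the vertex centroid by the
    linear factor sqrt(area_factor) (isotropic in-plane scaling is the
    unique similarity achieving a prescribed area change), and the scaled
    ring is translated so its centroid coincides with the original one.
    Out-of-plane jitter in the input is projected out before scaling.
    """
    if not np.isfinite(area_factor) or area_factor <= 0.0:
        raise GeometryError(f"area_factor must be positive, got {area_factor}")
    centroid = contour.centroid
    _, u, v = _plane_basis(contour.points)
    centred = contour.points - centroid
    in_plane = np.column_stack([centred @ u, centred @ v])
    scaled_2d = in_plane * np.sqrt(area_factor)
    scaled = centroid + scaled_2d[:, [0]] * u + scaled_2d[:, [1]] * v
    # Translate so the scaled centroid matches the original (identity in
    # exact arithmetic; kept explicit to pin the contract).
    scaled = scaled + (centroid - scaled.mean(axis=0))
    return Contour(scaled)


@dataclass(frozen=True)
class ContourStack:
    """Ordered stack of contours with fixed axial spacing (mm)."""

    contours: tuple[Contour, ...]
    spacing: float = 0.5  # mm between consecutive contour planes

    def __post_init__(self) -> None:
        contours = tuple(self.contours)
        if len(contours) < 2:
            raise GeometryError("a contour stack needs at least 2 contours")
        object.__setattr__(self, "contours", contours)

    def __len__(self) -> int:
        return len(self.contours)

    @property
    def points_per_contour(self) -> int:
        return self.contours[0].n_points

    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.contours])

    def areas(self) -> np.ndarray:
        return np.array([contour_area(c) for c in self.contours])

    def arc_positions(self) -> np.ndarray:
        """Cumulative centerline position of each contour plane, mm."""
        ctr = self.centroids()
        steps = np.linalg.norm(np.diff(ctr, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)])

    def validate(self, spacing_tol: float = 1e-6) -> None:
        """Check the spacing invariant (tolerance in mm)."""
        ctr = self.centroids()
        steps = np.linalg.norm(np.diff(ctr, axis=0), axis=1)
        bad = np.abs(steps - self.spacing) > spacing_tol
        if np.any(bad):
            idx = int(np.argmax(bad))
            raise GeometryError(
                f"contour spacing {steps[idx]:.6g} mm at station {idx} "
                f"differs from declared {self.spacing} mm"
            )

    def map_contours(self, fn) -> "ContourStack":
        return ContourStack(tuple(fn(c) for c in self.contours), self.spacing)


@dataclass(frozen=True)
class VesselModel:
    """Lumen + outer-wall contour stacks for one arterial segment."""

    case_id: str
    lumen: ContourStack
    outer_wall: ContourStack
    perturbation_tag: PerturbationTag = "original"

    def __post_init__(self) -> None:
        if len(self.lumen) != len(self.outer_wall):
            raise GeometryError(
                "lumen and outer wall must have the same number of contours "
                f"({len(self.lumen)} vs {len(self.outer_wall)})"
            )

    def validate(self) -> None:
        lumen_areas = self.lumen.areas()
        wall_areas = self.outer_wall.areas()
        if np.any(wall_areas < lumen_areas * (1.0 - 1e-9)):
            idx = int(np.argmax(wall_areas < lumen_areas))
            raise GeometryError(
                f"outer-wall area smaller than lumen area at station {idx}"
            )

    @property
    def n_stations(self) -> int:
        return len(self.lumen)


def perturb_vessel(
    vessel: VesselModel,
    error: float = 0.05,
    direction: Literal["over", "under"] = "under",
) -> VesselModel:
    """Apply a uniform per-contour area error to lumen and outer wall.

    ``direction='over'`` scales every contour area by (1 + error) —
    an overestimated reconstruction — and ``'under'`` by (1 − error).
    Centroids, point counts, contour ordering and axial spacing are all
    preserved; only the in-plane size changes.
    """
    if not (0.0 < error < 1.0):
        raise GeometryError(f"error fraction must be in (0, 1), got {error}")
    if direction not in ("over", "under"):
        raise GeometryError(f"direction must be 'over' or 'under', got {direction!r}")
    if vessel.perturbation_tag != "original":
        raise GeometryError("perturbation must start from an original-tagged vessel")
    factor = 1.0 + error if direction == "over" else 1.0 - error
    tag: PerturbationTag = "overestimated" if direction == "over" else "underestimated"
    scale = lambda c: scale_contour(c, factor)  # noqa: E731
    return VesselModel(
        case_id=vessel.case_id,
        lumen=vessel.lumen.map_contours(scale),
        outer_wall=vessel.outer_wall.map_contours(scale),
        perturbation_tag=tag,
    )


def make_error_models(
    vessel: VesselModel, error: float = 0.05
) -> tuple[VesselModel, VesselModel, VesselModel]:
    """Return the (original, overestimated, underestimated) triplet."""
    return (
        vessel,
        perturb_vessel(vessel, error, "over"),
        perturb_vessel(vessel, error, "under"),
    )


@dataclass(frozen=True)
class SurfaceMesh:
    """Open-ended triangulated tube lofted between consecutive contours."""

    vertices: np.ndarray  # (n_vertices, 3), mm
    triangles: np.ndarray  # (n_triangles, 3) int indices

    def __post_init__(self) -> None:
        verts = np.asarray(self.vertices, dtype=float)
        tris = np.asarray(self.triangles, dtype=np.int64)
        if tris.size and (tris.min() < 0 or tris.max() >= len(verts)):
            raise GeometryError("triangle indices out of range")
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "triangles", tris)

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @property
    def surface_area(self) -> float:
        """Total triangle area, mm²."""
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())


def loft_surface(stack: ContourStack) -> SurfaceMesh:
    """Loft a triangle-strip surface between corresponding ring vertices.

    Each quad between consecutive rings is split into two triangles, so a
    stack of n contours with p points each yields n·p vertices and
    2·(n−1)·p triangles.  The tube is open at both ends (no caps).
    """
    counts = {c.n_points for c in stack.contours}
    if len(counts) != 1:
        raise LoftError(f"contours have mismatched point counts: {sorted(counts)}")
    p = stack.points_per_contour
    vertices = np.vstack([c.points for c in stack.contours])
    tris = []
    for i in range(len(stack) - 1):
        a = i * p + np.arange(p)
        b = (i + 1) * p + np.arange(p)
        a_next = i * p + (np.arange(p) + 1) % p
        b_next = (i + 1) * p + (np.arange(p) + 1) % p
        tris.append(np.column_stack([a, b, b_next]))
        tris.append(np.column_stack([a, b_next, a_next]))
    return SurfaceMesh(vertices=vertices, triangles=np.vstack(tris))
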
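"""File formats: vessel contour stacks (CSV/JSON), cohort tables (CSV),
surface meshes (STL/OBJ) and YAML recipes/configs.

The contour CSV is a long table with columns
``case_id, surface, contour_index, point_index, x_mm, y_mm, z_mm``
(surface is ``lumen`` or ``wall``); coordinates are written with 17
significant digits so a write/read round trip is lossless well below
1e-9 mm.  The JSON schema carries the same content nested by surface
and contour.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .geometry import Contour, ContourStack, SurfaceMesh, VesselModel
from .prognostic import BIOHUMORAL_VARIABLES, CohortTable

__all__ = [
    "write_vessel_csv",
    "read_vessel_csv",
    "write_vessel_json",
    "read_vessel_json",
    "write_cohort_csv",
    "read_cohort_csv",
    "export_mesh",
    "load_yaml",
    "dump_yaml",
]

VESSEL_COLUMNS = [
    "case_id",
    "surface",
    "contour_index",
    "point_index",
    "x_mm",
    "y_mm",
    "z_mm",
]

_FLOAT_FMT = "%.17g"


def _vessel_frame(vessel: VesselModel) -> pd.DataFrame:
    records = []
    for surface, stack in (("lumen", vessel.lumen), ("wall", vessel.outer_wall)):
        for ci, contour in enumerate(stack.contours):
            for pi, (x, y, z) in enumerate(contour.points):
                records.append((vessel.case_id, surface, ci, pi, x, y, z))
    return pd.DataFrame(records, columns=VESSEL_COLUMNS)


def write_vessel_csv(vessel: VesselModel, path: str | Path) -> None:
    _vessel_frame(vessel).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _stack_from_frame(df: pd.DataFrame, spacing: float) -> ContourStack:
    contours = []
    for ci in sorted(df["contour_index"].unique()):
        ring = df[df["contour_index"] == ci].sort_values("point_index")
        contours.append(Contour(ring[["x_mm", "y_mm", "z_mm"]].to_numpy()))
    return ContourStack(tuple(contours), spacing=spacing)


def read_vessel_csv(
    path: str | Path, spacing: float = 0.5, perturbation_tag: str = "original"
) -> VesselModel:
    """Read a vessel from the long contour CSV.

    Malformed rows raise a FormatError naming the offending line.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # message carries the line number
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in VESSEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad = df[VESSEL_COLUMNS[4:]].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise FormatError(f"{path}: non-numeric or missing coordinate at line {line}")
    case_ids = df["case_id"].unique()
    if len(case_ids) != 1:
        raise FormatError(f"{path}: expected one case_id, found {list(case_ids)}")
    surfaces = set(df["surface"].unique())
    if surfaces != {"lumen", "wall"}:
        raise FormatError(f"{path}: surfaces must be lumen and wall, got {surfaces}")
    return VesselModel(
        case_id=str(case_ids[0]),
        lumen=_stack_from_frame(df[df["surface"] == "lumen"], spacing),
        outer_wall=_stack_from_frame(df[df["surface"] == "wall"], spacing),
        perturbation_tag=perturbation_tag,  # type: ignore[arg-type]
    )


def write_vessel_json(vessel: VesselModel, path: str | Path) -> None:
    payload: dict[str, Any] = {
        "case_id": vessel.case_id,
        "perturbation_tag": vessel.perturbation_tag,
        "spacing_mm": vessel.lumen.spacing,
        "surfaces": {
            name: [c.points.tolist() for c in stack.contours]
            for name, stack in (("lumen", vessel.lumen), ("wall", vessel.outer_wall))
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_vessel_json(path: str | Path) -> VesselModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"cannot parse {path}: line {exc.lineno}: {exc.msg}") from exc
    try:
        spacing = float(payload["spacing_mm"])
        stacks = {
            name: ContourStack(
                tuple(Contour(np.asarray(ring)) for ring in rings), spacing=spacing
            )
            for name, rings in payload["surfaces"].items()
        }
        return VesselModel(
            case_id=str(payload["case_id"]),
            lumen=stacks["lumen"],
            outer_wall=stacks["wall"],
            perturbation_tag=payload.get("perturbation_tag", "original"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: schema violation: {exc}") from exc


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cohort_csv(
    path: str | Path,
    biohumoral_columns: tuple[str, ...] = BIOHUMORAL_VARIABLES,
    outcome_column: str = "plaque_progression",
    outcome_kind: str = "continuous",
) -> CohortTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return CohortTable(
        data=df,
        biohumoral_columns=biohumoral_columns,
        outcome_column=outcome_column,
        outcome_kind=outcome_kind,  # type: ignore[arg-type]
    )


def export_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write a lofted surface as STL or OBJ (by file extension)."""
    suffix = Path(path).suffix.lower()
    if suffix not in (".stl", ".obj"):
        raise FormatError(f"unsupported mesh format {suffix!r} (use .stl or .obj)")
    mesh.to_trimesh().export(str(path))


def load_yaml(path: str | Path) -> Any:
    try:
        return yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def dump_yaml(obj: Any, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))
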
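"""SmartFFR: a computational surrogate of fractional flow reserve.

Pd/Pa is evaluated over a ramp of flow states (0, 1, 2, 3, 4 mL/s by
default), resampled with a shape-preserving monotone cubic spline to 100
points, and the area under this Pd/Pa-vs-flow curve is normalised by the
same quantity for a healthy reference segment of the same length
(constant radius, 95th-percentile station radius by default).  The ratio
is the SmartFFR value, in (0, 1]; values around the 0.80 clinical cutoff
form the grey zone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ProfileError
from .geometry import VesselModel
from .hemodynamics import AxialProfile, FlowConditions, axial_profile, pressure_profile

__all__ = [
    "PdPaCurve",
    "SmartFFRResult",
    "pdpa_curve",
    "healthy_reference",
    "compute_smartffr",
]

DEFAULT_FLOWS = (0.0, 1.0, 2.0, 3.0, 4.0)  # mL/s
N_SPLINE = 100


@dataclass(frozen=True)
class PdPaCurve:
    """Pd/Pa at the flow knots plus its 100-point spline resampling."""

    flows: np.ndarray  # mL/s
    values: np.ndarray  # Pd/Pa at the knots
    grid: np.ndarray  # 100-point flow grid spanning [flows[0], flows[-1]]
    spline_values: np.ndarray  # Pd/Pa on the grid

    @property
    def auc(self) -> float:
        """Trapezoidal area under the resampled curve."""
        return float(np.trapezoid(self.spline_values, self.grid))


@dataclass(frozen=True)
class SmartFFRResult:
    case_id: str
    perturbation_tag: str
    auc_case: float
    auc_healthy: float
    smartffr: float
    classification: Literal["healthy", "grey-zone", "ischemic"]


def _curve_from_profile(
    profile: AxialProfile,
    flows: Sequence[float],
    cond: FlowConditions,
    **pressure_kwargs,
) -> PdPaCurve:
    flows = np.asarray(flows, dtype=float)
    if len(flows) < 2 or np.any(np.diff(flows) <= 0):
        raise ProfileError("flows must be strictly increasing with >= 2 values")
    values = np.array(
        [
            pressure_profile(profile, replace(cond, flow=q), **pressure_kwargs).pd_over_pa
            for q in flows
        ]
    )
    grid = np.linspace(flows[0], flows[-1], N_SPLINE)
    spline = PchipInterpolator(flows, values)
    return PdPaCurve(flows=flows, values=values, grid=grid, spline_values=spline(grid))


def pdpa_curve(
    vessel: VesselModel,
    flows: Sequence[float] = DEFAULT_FLOWS,
    cond: FlowConditions = FlowConditions(),
    **pressure_kwargs,
) -> PdPaCurve:
    """Pd/Pa across the flow ramp, monotone-cubic resampled to 100 points.

    The spline is taken over flow (the ramp states map one-to-one onto
    flow levels), shape-preserving so the resampled curve cannot
    oscillate above 1 or below the knot range.
    """
    return _curve_from_profile(axial_profile(vessel), flows, cond, **pressure_kwargs)


def healthy_reference(
    vessel: VesselModel,
    flows: Sequence[float] = DEFAULT_FLOWS,
    cond: FlowConditions = FlowConditions(),
    reference_radius: float | None = None,
    radius_percentile: float = 95.0,
    **pressure_kwargs,
) -> PdPaCurve:
    """Pd/Pa curve of the vessel's idealised healthy counterpart.

    Same centerline length and stations, constant radius equal to the
    ``radius_percentile`` of the station radii (or an explicit
    ``reference_radius`` in mm).
    """
    profile = axial_profile(vessel)
    r_ref = (
        float(reference_radius)
        if reference_radius is not None
        else float(np.percentile(profile.radius, radius_percentile))
    )
    healthy = AxialProfile(z=profile.z, area=np.full_like(profile.z, np.pi * r_ref**2))
    return _curve_from_profile(healthy, flows, cond, **pressure_kwargs)


def classify(smartffr: float, cutoff: float = 0.80, band: float = 0.03) -> str:
    """Clinical call: grey zone is ``cutoff ± band``, ischemic below it."""
    if smartffr < cutoff - band:
        return "ischemic"
    if smartffr <= cutoff + band:
        return "grey-zone"
    return "healthy"


def compute_smartffr(
    vessel: VesselModel,
    flows: Sequence[float] = DEFAULT_FLOWS,
    cond: FlowConditions = FlowConditions(),
    cutoff: float = 0.80,
    band: float = 0.03,
    reference_radius: float | None = None,
    radius_percentile: float = 95.0,
    **pressure_kwargs,
) -> SmartFFRResult:
    """AUC ratio of the case curve to its healthy reference, clipped to 1."""
    case = pdpa_curve(vessel, flows, cond, **pressure_kwargs)
    ref = healthy_reference(
        vessel,
        flows,
        cond,
        reference_radius=reference_radius,
        radius_percentile=radius_percentile,
        **pressure_kwargs,
    )
    value = min(case.auc / ref.auc, 1.0)
    return SmartFFRResult(
        case_id=vessel.case_id,
        perturbation_tag=vessel.perturbation_tag,
        auc_case=case.auc,
        auc_healthy=ref.auc,
        smartffr=value,
        classification=classify(value, cutoff, band),
    )
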
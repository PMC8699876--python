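"""Reduced-order coronary hemodynamics.

Replaces a full 3-D Navier–Stokes solve with a one-dimensional model on
the per-station effective radius r(z) = sqrt(A(z)/pi):

* wall shear stress from the Poiseuille closed form
  tau(z) = 4 mu Q / (pi r(z)^3),
* pressure drop as the trapezoid integral of the Poiseuille gradient
  8 mu Q / (pi r(z)^4) plus a Young-type separation loss
  K_t (rho/2) (Q/A_ref)^2 (A_ref/A_throat - 1)^2 at each stenosis throat.

This preserves the monotone structure that matters for error
propagation: shrinking the lumen raises shear stress and the pressure
drop, enlarging it does the opposite.  Geometry is in mm, flow in mL/s,
pressures in mmHg externally; everything is converted to SI internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ProfileError
from .geometry import VesselModel

__all__ = [
    "MMHG_PA",
    "FlowConditions",
    "AxialProfile",
    "ESSField",
    "PressureProfile",
    "axial_profile",
    "compute_ess",
    "pressure_profile",
]

log = logging.getLogger(__name__)

MMHG_PA = 133.322  # 1 mmHg in Pa


@dataclass(frozen=True)
class FlowConditions:
    """Blood properties and boundary conditions.

    viscosity 0.0035 Pa·s (Newtonian blood), density 1060 kg/m³, mean
    aortic inlet pressure 100 mmHg, and a steady volumetric flow in
    mL/s (1 mL/s is average resting coronary flow).
    """

    viscosity: float = 0.0035  # Pa·s
    density: float = 1060.0  # kg/m³
    inlet_pressure: float = 100.0  # mmHg
    flow: float = 1.0  # mL/s

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0 or self.inlet_pressure <= 0:
            raise ProfileError("viscosity, density and inlet pressure must be > 0")
        if self.flow < 0:
            raise ProfileError("flow must be non-negative")


@dataclass(frozen=True)
class AxialProfile:
    """Per-station lumen geometry: z (mm), area (mm²), effective radius (mm)."""

    z: np.ndarray
    area: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        area = np.asarray(self.area, dtype=float)
        if z.shape != area.shape or z.ndim != 1:
            raise ProfileError("z and area must be 1-D arrays of equal length")
        if np.any(area <= 0):
            raise ProfileError("all lumen areas must be positive")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "area", area)

    @property
    def radius(self) -> np.ndarray:
        """Effective (area-equivalent) radius r = sqrt(A/pi), mm."""
        return np.sqrt(self.area / np.pi)

    @property
    def length(self) -> float:
        return float(self.z[-1] - self.z[0])


@dataclass(frozen=True)
class ESSField:
    """Ring-averaged wall shear stress per station, Pa."""

    z: np.ndarray  # mm
    tau: np.ndarray  # Pa
    conditions: FlowConditions


@dataclass(frozen=True)
class PressureProfile:
    """Axial pressure (mmHg), total drop and distal/proximal ratio."""

    z: np.ndarray  # mm
    pressure: np.ndarray  # mmHg
    dp: float  # mmHg, total drop inlet -> outlet
    pd_over_pa: float
    conditions: FlowConditions


def axial_profile(vessel: VesselModel) -> AxialProfile:
    """Lumen area/radius along the centerline from the contour stack."""
    return AxialProfile(
        z=vessel.lumen.arc_positions(),
        area=vessel.lumen.areas(),
    )


def compute_ess(
    profile: AxialProfile, cond: FlowConditions = FlowConditions()
) -> ESSField:
    """Poiseuille wall shear stress tau = 4 mu Q / (pi r^3) per station, Pa."""
    r_m = profile.radius * 1e-3
    if np.any(r_m <= 0):
        raise ProfileError("non-positive radius in profile")
    q_m3 = cond.flow * 1e-6
    tau = 4.0 * cond.viscosity * q_m3 / (np.pi * r_m**3)
    return ESSField(z=profile.z, tau=tau, conditions=cond)


def _stenosis_throats(
    area: np.ndarray, a_ref: float, threshold: float = 0.95
) -> list[int]:
    """Indices of stenosis throats: the area minimum of each contiguous
    run of stations whose area falls below ``threshold * a_ref``."""
    below = area < threshold * a_ref
    throats: list[int] = []
    i = 0
    n = len(area)
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            throats.append(i + int(np.argmin(area[i : j + 1])))
            i = j + 1
        else:
            i += 1
    return throats


def pressure_profile(
    profile: AxialProfile,
    cond: FlowConditions = FlowConditions(),
    kt: float = 1.52,
    include_separation: bool = True,
    reference_percentile: float = 95.0,
    pd_pa_floor: float = 0.0,
) -> PressureProfile:
    """Axial pressure from the Poiseuille gradient plus separation losses.

    The viscous drop is the trapezoid integral of 8 mu Q / (pi r^4); on a
    constant-radius tube this reduces exactly to the Poiseuille formula.
    For each detected stenosis a Young-type expansion loss
    ``kt * rho/2 * (Q/A_ref)^2 * (A_ref/A_throat - 1)^2`` is charged at
    the throat station (A_ref: the ``reference_percentile`` of the area
    profile).  Pd/Pa is floored at ``pd_pa_floor``; a negative distal
    pressure is flagged in the log and floored.
    """
    q_m3 = cond.flow * 1e-6
    r_m = profile.radius * 1e-3
    z_m = profile.z * 1e-3
    grad = 8.0 * cond.viscosity * q_m3 / (np.pi * r_m**4)  # Pa/m
    # cumulative trapezoid integral of the gradient
    dz = np.diff(z_m)
    drop = np.concatenate([[0.0], np.cumsum(0.5 * (grad[1:] + grad[:-1]) * dz)])

    if include_separation and cond.flow > 0:
        a_ref_mm2 = float(np.percentile(profile.area, reference_percentile))
        a_ref = a_ref_mm2 * 1e-6  # m²
        for idx in _stenosis_throats(profile.area, a_ref_mm2):
            a_throat = profile.area[idx] * 1e-6
            loss = (
                kt
                * 0.5
                * cond.density
                * (q_m3 / a_ref) ** 2
                * (a_ref / a_throat - 1.0) ** 2
            )
            drop = drop + np.where(np.arange(len(drop)) >= idx, loss, 0.0)

    p_in_pa = cond.inlet_pressure * MMHG_PA
    p_pa = p_in_pa - drop
    if p_pa[-1] < 0:
        log.warning(
            "distal pressure negative (%.3g Pa) — flooring Pd/Pa", p_pa[-1]
        )
    dp_mmhg = float(drop[-1] / MMHG_PA)
    pd_over_pa = max((cond.inlet_pressure - dp_mmhg) / cond.inlet_pressure, pd_pa_floor)
    return PressureProfile(
        z=profile.z,
        pressure=p_pa / MMHG_PA,
        dp=dp_mmhg,
        pd_over_pa=pd_over_pa,
        conditions=cond,
    )
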
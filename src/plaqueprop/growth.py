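"""Shear-coupled mechanistic plaque growth.

The causal chain: wall shear stress sets endothelial permeability;
Kedem–Katchalsky membrane relations give the volume and solute fluxes of
LDL, HDL and monocytes into the wall; a per-station system of ordinary
differential equations drives LDL oxidation, monocyte-to-macrophage
differentiation, foam-cell formation, cytokine signalling, contractile-
to-synthetic smooth-muscle-cell (SMC) conversion and collagen synthesis;
plaque volume (foam cells + synthetic SMCs + collagen) thickens the wall
and narrows the lumen, which feeds back into the shear field.

The wall is one axial compartment per contour station (no radial
resolution): that is the minimal structure that preserves the
shear -> permeability -> accumulation chain whose error sensitivity the
package quantifies.  Concentrations are arbitrary units; time is days.

A note on the direction of the geometric sensitivity: shear stress
scales as r^-3 while the permeability modulation P(tau) =
P0 (1 + a/(1 + b tau)) is deliberately mild (|dlnP/dlntau| < 1/3 at the
defaults), so the surface-to-volume ratio of the shrinking wall
compartment dominates and an undersized lumen accumulates species
faster — the behaviour observed when a segmentation error shrinks the
reconstruction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SimulationError
from .geometry import VesselModel, scale_contour
from .hemodynamics import (
    MMHG_PA,
    AxialProfile,
    FlowConditions,
    axial_profile,
    compute_ess,
)

__all__ = [
    "SPECIES",
    "KKParams",
    "GrowthParams",
    "LumenConcentrations",
    "WallState",
    "GrowthResult",
    "endothelial_flux",
    "wall_derivatives",
    "step_wall_odes",
    "run_growth",
    "plaque_summary",
]

log = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0

#: State variables of the wall cascade, in integration order.
SPECIES = (
    "ldl",
    "hdl",
    "oxldl",
    "monocytes",
    "macrophages",
    "foam_cells",
    "cytokines",
    "smc_contractile",
    "smc_synthetic",
    "collagen",
)

#: The summary roster: the ten wall species plus the two geometric outputs.
SUMMARY_VARIABLES = SPECIES + ("plaque_volume", "thickened_wall_area")


@dataclass(frozen=True)
class KKParams:
    """Kedem–Katchalsky membrane parameters.

    ``lp`` hydraulic conductivity (m s⁻¹ Pa⁻¹), ``sigma_d``/``sigma_f``
    osmotic and solvent-drag reflection coefficients, ``p0`` baseline
    solute permeability (m/s) modulated by shear as
    P(tau) = p0 (1 + a / (1 + b tau)) — strictly decreasing in tau, i.e.
    low shear enhances permeability.  ``dp`` transmural pressure and
    ``dpi`` osmotic pressure difference, Pa.
    """

    lp: float = 3.0e-12
    sigma_d: float = 0.9
    sigma_f: float = 0.9
    p0: float = 2.0e-10
    a: float = 1.0
    b: float = 1.0  # 1/Pa
    dp: float = 70.0 * MMHG_PA
    dpi: float = 2660.0

    def permeability(self, tau: np.ndarray | float) -> np.ndarray | float:
        return self.p0 * (1.0 + self.a / (1.0 + self.b * np.asarray(tau, float)))


def endothelial_flux(
    tau: np.ndarray | float,
    c_lumen: np.ndarray | float,
    c_wall: np.ndarray | float,
    kk: KKParams = KKParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Volume flux Jv (m/s) and solute flux Js (m/s · conc) across the
    endothelium.

    Jv = Lp (Δp − σd Δπ);  Js = P(τ)(C_l − C_w) + (1 − σf) Jv (C_l + C_w)/2.
    """
    tau = np.asarray(tau, dtype=float)
    c_lumen = np.asarray(c_lumen, dtype=float)
    c_wall = np.asarray(c_wall, dtype=float)
    if np.any(tau < 0):
        raise SimulationError("shear stress must be non-negative")
    if np.any(c_lumen < 0) or np.any(c_wall < 0):
        raise SimulationError("concentrations must be non-negative")
    jv = kk.lp * (kk.dp - kk.sigma_d * kk.dpi) * np.ones_like(tau)
    js = kk.permeability(tau) * (c_lumen - c_wall) + (1.0 - kk.sigma_f) * jv * (
        c_lumen + c_wall
    ) / 2.0
    return jv, js


@dataclass(frozen=True)
class LumenConcentrations:
    """Luminal (blood-side) concentrations, arbitrary units."""

    ldl: float = 1.0
    hdl: float = 1.0
    monocytes: float = 1.0


@dataclass(frozen=True)
class GrowthParams:
    """Rate constants of the wall cascade (per day unless noted).

    k_ox: LDL oxidation, attenuated by wall HDL via 1/(1 + k_h·HDL);
    k_m: monocyte-recruitment gain on oxLDL; k_dif: monocyte→macrophage
    differentiation; k_up: oxLDL uptake by macrophages (foam cells);
    k_c / d_cyt: cytokine production/decay; k_s: cytokine-driven
    contractile→synthetic SMC conversion; k_g / d_col: collagen synthesis
    and decay; d_*: first-order degradation rates.  w_*: weights of foam
    cells, synthetic SMCs and collagen in plaque volume.
    geometry_gain: lumen cross-section area removed per unit station
    plaque volume (mm² per a.u.).
    """

    k_ox: float = 0.5
    k_h: float = 0.5
    d_ldl: float = 0.1
    d_hdl: float = 0.1
    d_ox: float = 0.05
    k_m: float = 1.0
    k_dif: float = 0.5
    d_mac: float = 0.05
    k_up: float = 0.2
    k_c: float = 0.3
    d_cyt: float = 0.5
    k_s: float = 0.1
    k_g: float = 0.2
    d_col: float = 0.01
    w_foam: float = 1.0
    w_smc: float = 1.0
    w_collagen: float = 1.0
    smc_baseline: float = 1.0
    diseased_multiplier: float = 2.0  # initial contractile SMC scale-up
    perm_scale_ldl: float = 1.0
    perm_scale_hdl: float = 1.0
    perm_scale_monocytes: float = 0.1
    dt: float = 0.01  # days
    coupling_interval: float = 1.0  # days between geometry/shear updates
    t_end: float = 30.0  # days
    geometry_gain: float = 0.01  # mm² lumen-area loss per a.u. plaque volume
    min_radius: float = 0.1  # mm — lumen closure threshold

    def __post_init__(self) -> None:
        rates = (
            self.k_ox, self.k_h, self.d_ldl, self.d_hdl, self.d_ox, self.k_m,
            self.k_dif, self.d_mac, self.k_up, self.k_c, self.d_cyt, self.k_s,
            self.k_g, self.d_col,
        )
        if any(r < 0 for r in rates):
            raise SimulationError("all rate constants must be non-negative")
        if self.dt <= 0:
            raise SimulationError("dt must be positive")


@dataclass
class WallState:
    """Per-station wall concentrations plus cumulative wall thickening (mm)."""

    values: np.ndarray  # (len(SPECIES), n_stations)
    wall_thickening: np.ndarray  # (n_stations,), mm

    @classmethod
    def initial(cls, n_stations: int, params: GrowthParams) -> "WallState":
        values = np.zeros((len(SPECIES), n_stations))
        sc = SPECIES.index("smc_contractile")
        values[sc] = params.smc_baseline * params.diseased_multiplier
        return cls(values=values, wall_thickening=np.zeros(n_stations))

    def __getitem__(self, species: str) -> np.ndarray:
        return self.values[SPECIES.index(species)]

    def copy(self) -> "WallState":
        return WallState(self.values.copy(), self.wall_thickening.copy())


def wall_derivatives(
    values: np.ndarray,
    influx: Mapping[str, np.ndarray],
    params: GrowthParams,
) -> np.ndarray:
    """Right-hand side of the wall cascade.

    ``influx`` maps 'ldl' / 'hdl' / 'monocytes' to the per-station influx
    already multiplied by the compartment surface-to-volume ratio
    (units: concentration per day).
    """
    ldl, hdl, ox, mw, mac, _foam, cyt, sc, ss, _col = values
    oxidation = params.k_ox * ldl / (1.0 + params.k_h * hdl)
    d = np.empty_like(values)
    d[0] = influx["ldl"] - oxidation - params.d_ldl * ldl
    d[1] = influx["hdl"] - params.d_hdl * hdl
    d[2] = oxidation - params.k_up * ox * mac - params.d_ox * ox
    d[3] = influx["monocytes"] * (1.0 + params.k_m * ox) - params.k_dif * mw
    d[4] = params.k_dif * mw - params.d_mac * mac
    d[5] = params.k_up * ox * mac
    d[6] = params.k_c * mac - params.d_cyt * cyt
    d[7] = -params.k_s * cyt * sc
    d[8] = params.k_s * cyt * sc
    d[9] = params.k_g * ss - params.d_col * values[9]
    return d


_clip_warned = False


def step_wall_odes(
    state: WallState,
    influx: Mapping[str, np.ndarray],
    params: GrowthParams,
    dt: float,
) -> WallState:
    """One explicit classical Runge–Kutta (RK4) step of the wall cascade,
    clipped at zero.

    A step that would drive a species negative before clipping logs a
    stability warning once (the step size is too large for the stiffest
    rate present).
    """
    global _clip_warned
    y = state.values
    k1 = wall_derivatives(y, influx, params)
    k2 = wall_derivatives(y + 0.5 * dt * k1, influx, params)
    k3 = wall_derivatives(y + 0.5 * dt * k2, influx, params)
    k4 = wall_derivatives(y + dt * k3, influx, params)
    new_values = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if np.any(new_values < -1e-12) and not _clip_warned:
        log.warning("ODE step drove a species negative; clipping (reduce dt)")
        _clip_warned = True
    return WallState(np.clip(new_values, 0.0, None), state.wall_thickening.copy())


@dataclass
class GrowthResult:
    """Trajectory and final geometry of a growth simulation."""

    times: np.ndarray  # days, coupling-step resolution
    trajectory: dict[str, np.ndarray]  # variable -> (n_times, n_stations)
    plaque_volume: np.ndarray  # (n_times, n_stations), a.u.
    total_plaque_volume: np.ndarray  # (n_times,)
    thickened_wall_area: np.ndarray  # (n_times, n_stations), mm²
    vessel_out: VesselModel
    status: str  # 'completed' | 'lumen-closure'

    @property
    def final_total_plaque_volume(self) -> float:
        return float(self.total_plaque_volume[-1])


def _surface_to_volume(r_lumen_mm: np.ndarray, r_outer_mm: np.ndarray) -> np.ndarray:
    """S/V of the annular wall compartment, 1/m: 2 r_i / (r_o² − r_i²)."""
    r_i = r_lumen_mm * 1e-3
    r_o = r_outer_mm * 1e-3
    return 2.0 * r_i / (r_o**2 - r_i**2)


def run_growth(
    vessel: VesselModel,
    lumen: LumenConcentrations = LumenConcentrations(),
    kk: KKParams = KKParams(),
    params: GrowthParams = GrowthParams(),
    cond: FlowConditions = FlowConditions(),
) -> GrowthResult:
    """Coupled shear / transport / growth loop.

    Every ``coupling_interval`` days the shear field is recomputed from
    the current lumen radii; within the interval the wall cascade is
    integrated with step ``dt``, with the endothelial fluxes re-evaluated
    each step from the current wall concentrations.  Station plaque
    volume V_p = w_F·F + w_S·S_s + w_G·G removes
    ``geometry_gain × V_p`` mm² of lumen area; the run halts with status
    ``'lumen-closure'`` if any station radius reaches ``min_radius``.
    """
    profile0 = axial_profile(vessel)
    area0 = profile0.area.copy()
    r0 = profile0.radius.copy()
    r_outer = np.sqrt(vessel.outer_wall.areas() / np.pi)
    n = len(area0)

    state = WallState.initial(n, params)
    area = area0.copy()
    status = "completed"

    times = [0.0]
    traj: dict[str, list[np.ndarray]] = {v: [] for v in SUMMARY_VARIABLES}
    for i, name in enumerate(SPECIES):
        traj[name].append(state.values[i].copy())
    traj["plaque_volume"].append(np.zeros(n))
    traj["thickened_wall_area"].append(np.zeros(n))

    perm_scale = {
        "ldl": params.perm_scale_ldl,
        "hdl": params.perm_scale_hdl,
        "monocytes": params.perm_scale_monocytes,
    }
    lumen_conc = {"ldl": lumen.ldl, "hdl": lumen.hdl, "monocytes": lumen.monocytes}

    n_coupling = int(round(params.t_end / params.coupling_interval))
    n_sub = max(1, int(round(params.coupling_interval / params.dt)))
    dt = params.coupling_interval / n_sub
    t = 0.0
    for _ in range(n_coupling):
        r = np.sqrt(area / np.pi)
        tau = compute_ess(AxialProfile(z=profile0.z, area=area), cond).tau
        s_over_v = _surface_to_volume(r, r_outer)
        for _ in range(n_sub):
            influx = {}
            for name in ("ldl", "hdl", "monocytes"):
                _, js = endothelial_flux(tau, lumen_conc[name], state[name], kk)
                influx[name] = perm_scale[name] * js * s_over_v * SECONDS_PER_DAY
            state = step_wall_odes(state, influx, params, dt)
        t += params.coupling_interval

        vp = (
            params.w_foam * state["foam_cells"]
            + params.w_smc * state["smc_synthetic"]
            + params.w_collagen * state["collagen"]
        )
        area = area0 - params.geometry_gain * vp
        if np.any(area <= np.pi * params.min_radius**2):
            area = np.maximum(area, np.pi * params.min_radius**2)
            status = "lumen-closure"
        state.wall_thickening = r0 - np.sqrt(area / np.pi)

        times.append(t)
        for i, name in enumerate(SPECIES):
            traj[name].append(state.values[i].copy())
        traj["plaque_volume"].append(vp.copy())
        traj["thickened_wall_area"].append(area0 - area)
        if status == "lumen-closure":
            log.warning("lumen closure at t=%.2f days; halting growth", t)
            break

    # regenerate lumen contours at the final narrowed areas
    factors = area / area0
    new_contours = tuple(
        scale_contour(c, float(f))
        for c, f in zip(vessel.lumen.contours, factors)
    )
    vessel_out = VesselModel(
        case_id=vessel.case_id,
        lumen=type(vessel.lumen)(new_contours, vessel.lumen.spacing),
        outer_wall=vessel.outer_wall,
        perturbation_tag=vessel.perturbation_tag,
    )

    trajectory = {k: np.array(v) for k, v in traj.items()}
    pv = trajectory["plaque_volume"]
    return GrowthResult(
        times=np.array(times),
        trajectory=trajectory,
        plaque_volume=pv,
        total_plaque_volume=pv.sum(axis=1),
        thickened_wall_area=trajectory["thickened_wall_area"],
        vessel_out=vessel_out,
        status=status,
    )


def plaque_summary(result: GrowthResult, ddof: int = 0) -> pd.DataFrame:
    """Across-station min/max/mean/sd of the twelve output variables at
    the final time.

    ``ddof=0`` gives the population standard deviation, ``ddof=1`` the
    sample convention.
    """
    rows = {}
    for name in SUMMARY_VARIABLES:
        x = result.trajectory[name][-1]
        rows[name] = {
            "min": float(x.min()),
            "max": float(x.max()),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=ddof)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")[["min", "max", "mean", "sd"]]
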
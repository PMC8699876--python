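"""End-to-end orchestration: synthetic vessels -> ±error triplets ->
shear stress -> SmartFFR -> plaque growth -> agreement statistics ->
error-injected prognosis.

A run directory is self-describing: it contains the resolved config,
the global seed, and a manifest with a config hash and the SHA-256 of
every output file, so re-running the same config reproduces the
directory bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import SimulationError
from .geometry import make_error_models
from .growth import GrowthParams, KKParams, run_growth
from .hemodynamics import FlowConditions, axial_profile, compute_ess, pressure_profile
from .io import dump_yaml, write_cohort_csv, write_vessel_csv
from .prognostic import (
    ErrorScenario,
    compare_scenarios,
    inject_error,
    univariate_screen,
)
from .smartffr import compute_smartffr
from .stats import (
    PairedComparison,
    bland_altman,
    max_relative_error,
    paired_stats,
    pearson_r,
    propagate_uncertainty,
    relative_error_summary,
)
from .synthetic import CohortRecipe, StenosisSpec, VesselRecipe, child_seeds, generate_cohort, generate_vessel

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Validated configuration of a full pipeline run."""

    n_vessels: int = Field(default=3, ge=1)
    error_fraction: float = Field(default=0.05, gt=0.0, lt=1.0)
    vessel_length: float = Field(default=30.0, gt=0.0)
    base_radius: float = Field(default=1.5, gt=0.0)
    wall_thickness: float = Field(default=0.5, gt=0.0)
    severity_range: tuple[float, float] = (0.2, 0.7)
    rest_flow_ml_s: float = Field(default=1.0, ge=0.0)
    inlet_pressure_mmhg: float = Field(default=100.0, gt=0.0)
    viscosity_pa_s: float = Field(default=0.0035, gt=0.0)
    density_kg_m3: float = Field(default=1060.0, gt=0.0)
    kt: float = Field(default=1.52, ge=0.0)
    separation_term: bool = True
    flows_ml_s: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0)
    run_growth: bool = True
    growth_t_end_days: float = Field(default=10.0, gt=0.0)
    run_prognosis: bool = True
    cohort_n_patients: int = Field(default=200, ge=10)
    reconstruction_uncertainty: float = Field(default=0.09, ge=0.0)
    seed: int = 0

    @field_validator("severity_range")
    @classmethod
    def _check_severities(cls, v: tuple[float, float]) -> tuple[float, float]:
        lo, hi = v
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("severity_range must satisfy 0 <= lo <= hi < 1")
        return v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _flow_conditions(config: PipelineConfig, flow: float) -> FlowConditions:
    return FlowConditions(
        viscosity=config.viscosity_pa_s,
        density=config.density_kg_m3,
        inlet_pressure=config.inlet_pressure_mmhg,
        flow=flow,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute every stage and return the run directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "vessels").mkdir(exist_ok=True)
    manifest: dict = {"version": __version__, "stages": {}, "outputs": {}}

    seeds = child_seeds(config.seed, config.n_vessels + 2)
    vessel_seeds, cohort_seed, scenario_seed = (
        seeds[: config.n_vessels],
        seeds[-2],
        seeds[-1],
    )
    manifest["seed"] = config.seed

    try:
        # --- stage: vessels ------------------------------------------------
        severities = np.linspace(*config.severity_range, config.n_vessels)
        triplets = []
        for i, (sev, vseed) in enumerate(zip(severities, vessel_seeds)):
            recipe = VesselRecipe(
                length=config.vessel_length,
                base_radius=config.base_radius,
                wall_thickness=config.wall_thickness,
                stenoses=(
                    StenosisSpec(
                        center=config.vessel_length / 2.0,
                        length=config.vessel_length / 3.0,
                        severity=float(sev),
                    ),
                ),
                seed=vseed,
                case_id=f"vessel_{i:03d}",
            )
            original = generate_vessel(recipe)
            triplet = make_error_models(original, config.error_fraction)
            triplets.append(triplet)
            for model in triplet:
                write_vessel_csv(
                    model, out / "vessels" / f"{model.case_id}_{model.perturbation_tag}.csv"
                )
        manifest["stages"]["vessels"] = {"n_models": 3 * config.n_vessels}

        # --- stage: hemodynamics -------------------------------------------
        cond = _flow_conditions(config, config.rest_flow_ml_s)
        ess_rows = []
        for triplet in triplets:
            for model in triplet:
                profile = axial_profile(model)
                ess = compute_ess(profile, cond)
                pres = pressure_profile(
                    profile,
                    cond,
                    kt=config.kt,
                    include_separation=config.separation_term,
                )
                for z, a, r, tau, p in zip(
                    profile.z, profile.area, profile.radius, ess.tau, pres.pressure
                ):
                    ess_rows.append(
                        (model.case_id, model.perturbation_tag, z, a, r, tau, p)
                    )
        ess_df = pd.DataFrame(
            ess_rows,
            columns=["case_id", "tag", "z_mm", "area_mm2", "radius_mm", "tau_Pa", "P_mmHg"],
        )
        ess_df.to_csv(out / "ess.csv", index=False)
        manifest["stages"]["hemodynamics"] = {"rows": len(ess_df)}

        # --- stage: smartffr -----------------------------------------------
        ffr_rows = []
        for triplet in triplets:
            for model in triplet:
                res = compute_smartffr(
                    model,
                    flows=config.flows_ml_s,
                    cond=cond,
                    kt=config.kt,
                    include_separation=config.separation_term,
                )
                ffr_rows.append(
                    (
                        res.case_id,
                        res.perturbation_tag,
                        res.smartffr,
                        res.classification,
                        res.auc_case,
                        res.auc_healthy,
                    )
                )
        ffr_df = pd.DataFrame(
            ffr_rows,
            columns=["case_id", "tag", "smartffr", "classification", "auc_case", "auc_healthy"],
        )
        ffr_df.to_csv(out / "smartffr.csv", index=False)
        manifest["stages"]["smartffr"] = {"rows": len(ffr_df)}

        # --- stage: growth --------------------------------------------------
        growth_df = None
        if config.run_growth:
            params = GrowthParams(t_end=config.growth_t_end_days)
            growth_rows = []
            for triplet in triplets:
                for model in triplet:
                    res = run_growth(model, params=params, cond=cond)
                    growth_rows.append(
                        (
                            model.case_id,
                            model.perturbation_tag,
                            res.final_total_plaque_volume,
                            float(res.thickened_wall_area[-1].sum()),
                            res.status,
                        )
                    )
            growth_df = pd.DataFrame(
                growth_rows,
                columns=["case_id", "tag", "total_plaque_volume", "thickened_wall_area_mm2", "status"],
            )
            growth_df.to_csv(out / "growth.csv", index=False)
            manifest["stages"]["growth"] = {"rows": len(growth_df)}

        # --- stage: statistics ----------------------------------------------
        stats_rows = []
        pooled = ess_df.pivot_table(
            index=["case_id", "z_mm"], columns="tag", values="tau_Pa"
        )
        u_prev = config.reconstruction_uncertainty
        for tag in ("overestimated", "underestimated"):
            comp = PairedComparison(
                pooled["original"].to_numpy(), pooled[tag].to_numpy()
            )
            mean, sd = paired_stats(comp)
            ba = bland_altman(comp)
            r, p = pearson_r(pooled["original"], pooled[tag])
            orig_stats = (
                pooled["original"].min(),
                pooled["original"].max(),
                pooled["original"].mean(),
            )
            pert_stats = (pooled[tag].min(), pooled[tag].max(), pooled[tag].mean())
            re = relative_error_summary(orig_stats, pert_stats)
            stats_rows.append(
                {
                    "level": "ess",
                    "tag": tag,
                    "mean_diff": mean,
                    "sd_diff": sd,
                    "loa_low": ba.loa_low,
                    "loa_high": ba.loa_high,
                    "pearson_r": r,
                    "re_min": re.re_min,
                    "re_max": re.re_max,
                    "re_mean": re.re_mean,
                    "uncertainty": propagate_uncertainty(sd, u_prev),
                }
            )
        ffr_wide = ffr_df.pivot_table(index="case_id", columns="tag", values="smartffr")
        for tag in ("overestimated", "underestimated"):
            comp = PairedComparison(
                ffr_wide["original"].to_numpy(), ffr_wide[tag].to_numpy()
            )
            mean, sd = paired_stats(comp)
            r, p = pearson_r(ffr_wide["original"], ffr_wide[tag])
            max_re, _ = max_relative_error(ffr_wide["original"], ffr_wide[tag])
            stats_rows.append(
                {
                    "level": "smartffr",
                    "tag": tag,
                    "mean_diff": mean,
                    "sd_diff": sd,
                    "pearson_r": r,
                    "max_relative_error_pct": max_re,
                }
            )
        if growth_df is not None:
            gw = growth_df.pivot_table(
                index="case_id", columns="tag", values="total_plaque_volume"
            )
            ess_sd = {
                row["tag"]: row["sd_diff"] for row in stats_rows if row["level"] == "ess"
            }
            for tag in ("overestimated", "underestimated"):
                comp = PairedComparison(
                    gw["original"].to_numpy(), gw[tag].to_numpy()
                )
                mean, sd = paired_stats(comp)
                u_level2 = propagate_uncertainty(ess_sd[tag], u_prev)
                stats_rows.append(
                    {
                        "level": "growth",
                        "tag": tag,
                        "mean_diff": mean,
                        "sd_diff": sd,
                        "uncertainty": propagate_uncertainty(sd, u_level2),
                    }
                )
        pd.DataFrame(stats_rows).to_csv(out / "comparison_stats.csv", index=False)
        manifest["stages"]["statistics"] = {"rows": len(stats_rows)}

        # --- stage: prognosis -------------------------------------------------
        if config.run_prognosis:
            cohort = generate_cohort(
                CohortRecipe(n_patients=config.cohort_n_patients, seed=cohort_seed)
            )
            write_cohort_csv(cohort, out / "cohort.csv")
            scenarios = {
                "original": ErrorScenario(kind="none"),
                "maximum": ErrorScenario(kind="maximum"),
                "random": ErrorScenario(kind="random", seed=scenario_seed),
            }
            reports = {
                name: univariate_screen(inject_error(cohort, sc))
                for name, sc in scenarios.items()
            }
            pattern = compare_scenarios(reports)
            for name, rep in reports.items():
                rep.table.to_csv(out / f"univariate_{name}.csv")
            pattern.to_csv(out / "significance_pattern.csv")
            manifest["stages"]["prognosis"] = {
                "jaccard": {f"{a}|{b}": v for (a, b), v in pattern.attrs["jaccard"].items()}
            }
    except Exception as exc:
        manifest["failed_stage"] = type(exc).__name__
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise SimulationError(f"pipeline stage failed: {exc}") from exc

    # --- manifest ----------------------------------------------------------
    config_payload = config.model_dump()
    dump_yaml(config_payload, out / "config.yaml")
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(config_payload, sort_keys=True, default=str).encode()
    ).hexdigest()
    for path in sorted(out.rglob("*.csv")):
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
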
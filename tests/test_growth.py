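import dataclasses

import numpy as np
import pytest

from plaqueprop.errors import SimulationError
from plaqueprop.geometry import make_error_models
from plaqueprop.growth import (
    SPECIES,
    SUMMARY_VARIABLES,
    GrowthParams,
    KKParams,
    LumenConcentrations,
    WallState,
    endothelial_flux,
    plaque_summary,
    run_growth,
    step_wall_odes,
    wall_derivatives,
)

FAST = GrowthParams(t_end=5.0, coupling_interval=1.0, dt=0.01)


class TestEndothelialFlux:
    def test_closed_membrane(self):
        kk = KKParams(lp=0.0, p0=0.0)
        jv, js = endothelial_flux(1.0, 1.0, 0.0, kk)
        assert jv == 0.0 and js == 0.0

    def test_no_gradient_no_diffusion(self):
        kk = KKParams(lp=0.0)
        _, js = endothelial_flux(2.0, 0.7, 0.7, kk)
        assert js == pytest.approx(0.0, abs=1e-30)

    def test_low_shear_enhances_solute_flux(self):
        kk = KKParams(lp=0.0)
        _, js_low = endothelial_flux(0.5, 1.0, 0.0, kk)
        _, js_high = endothelial_flux(3.0, 1.0, 0.0, kk)
        assert js_low > js_high

    def test_permeability_strictly_decreasing(self):
        kk = KKParams()
        taus = np.linspace(0.0, 10.0, 50)
        assert np.all(np.diff(kk.permeability(taus)) < 0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(SimulationError):
            endothelial_flux(1.0, -0.1, 0.0)


ZERO_INFLUX = {"ldl": np.zeros(4), "hdl": np.zeros(4), "monocytes": np.zeros(4)}


def _zero_rate_params(**overrides) -> GrowthParams:
    zeros = {
        f.name: 0.0
        for f in dataclasses.fields(GrowthParams)
        if f.name.startswith(("k_", "d_"))
    }
    zeros.update(overrides)
    return GrowthParams(**zeros)


class TestWallOdes:
    def test_zero_rates_zero_influx_state_fixed(self):
        params = _zero_rate_params()
        state = WallState.initial(4, params)
        stepped = step_wall_odes(state, ZERO_INFLUX, params, 0.5)
        assert np.array_equal(stepped.values, state.values)

    def test_no_uptake_keeps_foam_cells_constant(self):
        params = GrowthParams(k_up=0.0)
        state = WallState.initial(4, params)
        state.values[SPECIES.index("oxldl")] = 1.0
        state.values[SPECIES.index("macrophages")] = 1.0
        for _ in range(100):
            state = step_wall_odes(state, ZERO_INFLUX, params, 0.01)
        assert np.allclose(state["foam_cells"], 0.0)

    def test_explicit_step_matches_fine_step_oracle(self):
        """Single-compartment run at dt agrees with an independent
        brute-force Euler integration at dt/100 of the same right-hand
        side to 0.1%."""
        params = GrowthParams(dt=0.01)
        influx = {"ldl": np.array([0.3]), "hdl": np.array([0.2]), "monocytes": np.array([0.05])}
        t_end, dt = 5.0, 0.01

        state = WallState.initial(1, params)
        for _ in range(int(round(t_end / dt))):
            state = step_wall_odes(state, influx, params, dt)

        # oracle: plain forward-Euler on the raw derivatives at dt/100
        fine = WallState.initial(1, params).values
        fine_dt = dt / 100.0
        for _ in range(int(round(t_end / fine_dt))):
            fine = np.clip(fine + fine_dt * wall_derivatives(fine, influx, params), 0.0, None)

        rel = np.abs(state.values - fine) / np.maximum(np.abs(fine), 1e-12)
        assert rel.max() < 1e-3

    def test_conservation_without_sinks(self):
        """With degradation and oxidation off, wall LDL equals the time
        integral of its influx (fine-step oracle) within 1%."""
        params = _zero_rate_params()
        influx = {"ldl": np.array([0.4]), "hdl": np.array([0.0]), "monocytes": np.array([0.0])}
        state = WallState.initial(1, params)
        t_end, dt = 10.0, 0.01
        for _ in range(int(t_end / dt)):
            state = step_wall_odes(state, influx, params, dt)
        assert state["ldl"][0] == pytest.approx(0.4 * t_end, rel=1e-2)


class TestRunGrowth:
    def test_closed_membrane_leaves_vessel_untouched(self, stenosed_vessel):
        kk = KKParams(lp=0.0, p0=0.0)
        result = run_growth(stenosed_vessel, kk=kk, params=FAST)
        assert result.final_total_plaque_volume == 0.0
        for c_in, c_out in zip(stenosed_vessel.lumen.contours, result.vessel_out.lumen.contours):
            assert np.allclose(c_in.points, c_out.points, atol=1e-12)

    def test_perturbation_ordering_of_plaque_volume(self, triplet):
        original, over, under = triplet
        totals = {
            m.perturbation_tag: run_growth(m, params=FAST).final_total_plaque_volume
            for m in (original, over, under)
        }
        assert totals["underestimated"] >= totals["original"] >= totals["overestimated"]

    def test_thickened_wall_area_increases_without_degradation(self, stenosed_vessel):
        params = dataclasses.replace(
            FAST, d_ldl=0.0, d_hdl=0.0, d_ox=0.0, d_mac=0.0, d_cyt=0.0, d_col=0.0
        )
        result = run_growth(stenosed_vessel, params=params)
        totals = result.thickened_wall_area.sum(axis=1)
        assert np.all(np.diff(totals) > 0)

    def test_monotone_propagation_of_influx_species(self, triplet):
        original, _, under = triplet
        res_o = run_growth(original, params=FAST)
        res_u = run_growth(under, params=FAST)
        for name in ("ldl", "hdl", "monocytes", "macrophages", "foam_cells"):
            assert res_u.trajectory[name][-1].mean() >= res_o.trajectory[name][-1].mean()

    def test_determinism(self, stenosed_vessel):
        a = run_growth(stenosed_vessel, params=FAST)
        b = run_growth(stenosed_vessel, params=FAST)
        for name in SUMMARY_VARIABLES:
            assert np.array_equal(a.trajectory[name], b.trajectory[name])

    def test_lumen_closure_halts_with_status(self, stenosed_vessel):
        params = dataclasses.replace(FAST, geometry_gain=50.0, t_end=30.0)
        result = run_growth(stenosed_vessel, params=params)
        assert result.status == "lumen-closure"
        assert np.all(result.vessel_out.lumen.areas() >= np.pi * params.min_radius**2 - 1e-9)


class TestPlaqueSummary:
    def test_roster_is_the_twelve_output_variables(self, straight_vessel):
        summary = plaque_summary(run_growth(straight_vessel, params=FAST))
        assert list(summary.index) == list(SUMMARY_VARIABLES)
        assert len(summary) == 12
        assert list(summary.columns) == ["min", "max", "mean", "sd"]

    def test_constant_state_collapses(self, straight_vessel):
        kk = KKParams(lp=0.0, p0=0.0)
        summary = plaque_summary(run_growth(straight_vessel, kk=kk, params=FAST))
        row = summary.loc["ldl"]
        assert row["min"] == row["max"] == row["mean"]
        assert row["sd"] == 0.0

    def test_sd_convention_toggle(self, stenosed_vessel):
        result = run_growth(stenosed_vessel, params=FAST)
        pop = plaque_summary(result, ddof=0)
        samp = plaque_summary(result, ddof=1)
        n = result.trajectory["ldl"].shape[1]
        ratio = samp["sd"]["ldl"] / pop["sd"]["ldl"]
        assert ratio == pytest.approx(np.sqrt(n / (n - 1)), rel=1e-9)
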
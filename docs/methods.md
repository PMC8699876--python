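# Methods

`plaqueprop` quantifies how a systematic error in reconstructed coronary
geometry propagates through three simulation levels — wall shear stress,
the SmartFFR diagnostic index, and a mechanistic plaque-growth model —
and how analytical laboratory error perturbs a prognostic regression of
plaque progression. This note records the models, the defaults and the
design choices behind them.

## Vessel representation and the area perturbation

A segment is two stacks of closed planar contours (lumen and outer
wall), 72 points per ring, planes 0.5 mm apart along the centerline,
coordinates in mm. The perturbation emulates a segmentation error of a
stated fraction e (default 0.05): every contour is scaled isotropically
in its own best-fit plane about its *vertex* centroid by the linear
factor sqrt(1 ± e), then translated so the centroid is preserved. The
enclosed (shoelace) area therefore changes by exactly 1 ± e at every
station, which is the module's central contract (verified to 1e-9
relative).

Choices worth noting:

* **Vertex centroid, not area centroid.** For the regular synthetic
  rings they coincide; for irregular rings the vertex mean matches a
  point-cloud workflow. The scaling routine is written against the
  centroid accessor, so swapping the definition is a one-line change.
* **Out-of-plane jitter is projected out before scaling**, so the area
  contract is exact even for slightly non-planar input rings.
* Both surfaces are perturbed in the same direction by default, since
  the error model applies the same procedure to lumen and outer wall.

Surfaces are lofted as triangle strips between corresponding vertices
of consecutive rings (2·(n−1)·72 triangles), exported via trimesh as
STL/OBJ.

## Reduced-order hemodynamics

The package deliberately replaces 3-D CFD with a one-dimensional model
on the effective radius r(z) = sqrt(A(z)/π). What is being studied is
the *propagation of a geometric error*, not the flow solver; the
reduced model preserves the structure that propagation depends on:

* **Shear stress**: τ(z) = 4μQ/(πr³) (Poiseuille), μ = 0.0035 Pa·s,
  rest flow Q = 1 mL/s. A uniform area error f multiplies τ by
  f^(−3/2) at every station — the exact module-level propagated-error
  law. At the ±5% setting this is +8.00% (under) / −7.06% (over) in
  mean shear, the reduced-order analogue of the few-percent mean shifts
  a full CFD study reports.
* **Pressure**: trapezoid integral of the Poiseuille gradient 8μQ/(πr⁴)
  plus a Young-type separation loss K_t·(ρ/2)·(Q/A_ref)²·(A_ref/A_t−1)²
  charged at each detected stenosis throat (contiguous region with
  A < 0.95·A_ref; A_ref is the 95th-percentile area). Defaults
  K_t = 1.52, ρ = 1060 kg/m³ (density is a package choice; only the
  viscosity is inherited from the study conditions). The separation
  term can be disabled for a pure viscous model.
* Units: mm/mL·s/mmHg at the interface, SI internally,
  1 mmHg = 133.322 Pa. On a constant tube the pressure drop matches the
  analytic Poiseuille value to 1e-6 relative (tested).

## SmartFFR

Pd/Pa is evaluated over the flow ramp 0–4 mL/s (five states, inlet
pressure 100 mmHg), interpolated over *flow* with a shape-preserving
monotone cubic (PCHIP) and resampled to 100 points including both
endpoints; the ramp states map one-to-one to flow levels, and the
monotone spline cannot oscillate, which keeps the AUC stable. SmartFFR
is the trapezoidal AUC divided by the AUC of a healthy reference —
the same stations at constant radius, by default the 95th percentile of
the station radii (configurable: explicit radius). The ratio is clipped
to 1; classification uses the clinical 0.80 cutoff with a ±0.03 grey
zone (both configurable). A healthy tube self-normalises to 1.000
within 1e-6.

## Plaque growth

The wall is one axial compartment per station. Transport across the
endothelium follows the Kedem–Katchalsky relations

    Jv = Lp(Δp − σd·Δπ),
    Js = P(τ)(C_l − C_w) + (1 − σf)·Jv·(C_l + C_w)/2,

with a low-shear permeability enhancement P(τ) = P0·(1 + a/(1 + bτ)),
strictly decreasing in τ. Defaults: Lp = 3e-12 m/(s·Pa), σd = σf = 0.9,
P0 = 2e-10 m/s, a = 1, b = 1 Pa⁻¹, Δp = 70 mmHg, Δπ = 2660 Pa.
Monocyte transport is scaled to 10% of the solute permeability (cells
cross far less readily than lipoproteins).

Inside the wall a ten-species cascade runs in arbitrary concentration
units with time in days: LDL oxidation attenuated by HDL
(k_ox/(1 + k_h·HDL)), monocyte recruitment amplified by oxLDL,
monocyte→macrophage differentiation, foam-cell formation by oxLDL
uptake, cytokine production, cytokine-driven contractile→synthetic SMC
conversion (initial contractile pool: baseline × a "diseased"
multiplier, default 2), collagen synthesis, and first-order decay
terms. The source study names these mechanisms without printing its
equation system; the system here is the minimal ODE set realising every
named mechanism, with every rate exposed in `GrowthParams`. Absolute
concentration magnitudes are therefore not comparable to any particular
patient dataset and are not treated as targets.

Integration is an explicit classical Runge–Kutta (RK4) step, dt = 0.01
day, states clipped at zero with a one-shot stability warning; a
dt/100 brute-force Euler oracle agrees to better than 0.1% (tested).
Shear and geometry are refreshed every coupling interval (1 day).
Station plaque volume V_p = w_F·F + w_S·S_s + w_G·G removes
`geometry_gain` (0.01 mm² per unit V_p) of lumen area, chosen so the
default 10–30-day horizon produces mild (sub-percent to few-percent)
lumen loss; the run halts with a documented status if any radius
reaches 0.1 mm.

**Direction of the geometric sensitivity.** An undersized lumen raises
τ, which *lowers* P(τ); on its own that would slow accumulation. But
the same error shrinks the wall compartment, raising its
surface-to-volume ratio S/V = 2r_i/(r_o² − r_i²) by f^(−1/2).
Per-volume influx scales as P(τ(r))·S/V, and with the default mild
permeability elasticity (|d ln P/d ln τ| < 1/3 for a ≤ 2.5) the S/V
channel dominates, so underestimation accelerates accumulation and
growth while overestimation slows it — the ordering
under ≥ original ≥ over in total plaque volume that the pipeline
asserts. Choosing a steeper shear–permeability law (large a·b) can
invert this; the constraint is the price of keeping both the low-shear
enhancement and the observed direction in one compartment model.

## Statistics

* Paired differences are `original − perturbed`; this convention
  reproduces the signs of the reference SmartFFR mean differences
  (−0.004 over, +0.009 under). A flag flips it.
* Standard deviations default to the population convention (ddof 0),
  which matches the printed spreads of the reference comparisons at
  their printed precision; the sample convention is available
  everywhere (including the growth summary).
* Bland–Altman limits are mean ± 1.96·sd, with the standard
  large-sample CI of each limit, half-width 1.96·sqrt(3·sd²/n); n is a
  parameter because reference point counts are rarely printed.
* Relative errors of summary statistics are 100·(pert − orig)/orig,
  applied elementwise to (min, max, mean).
* Multi-level uncertainty chains in quadrature, u = sqrt(sd² + u²_prev),
  seeded with the reconstruction-level uncertainty 0.09.

The bundled reference tables (`plaqueprop.datasets`) anchor these
routines. Two published cells are deliberately *not* asserted: the
overestimated-shear agreement limits are inconsistent with
mean ± 1.96·sd of their own printed inputs (flagged
`consistent=False`), and the thickened-wall relative-error mean does
not recompute from its printed means — both are documented exclusions,
exercised by a test that verifies the mismatch.

## Prognostic stability

Cohorts carry a 16-variable biohumoral roster, four lipidomic species,
age, baseline plaque burden, simulation-derived features and a
progression outcome. Analytical error is injected only into the
biohumoral columns: ×1.13 everywhere (worst-case 13% analytical error;
direction configurable) or i.i.d. uniform multipliers on [0.87, 1.13]
per cell (per-column mode available). Screening is per-variable OLS
with Wald CIs by default — the reference multivariate table is linear —
with logistic regression first-class for binary outcomes; no
multiple-testing correction is applied by default (matching the
source analysis; Benjamini–Hochberg could be layered on by the user).
Because OLS is scale-equivariant, the uniform scenario changes
coefficients by exactly 1/1.13 and p-values not at all, so the
significant set is invariant — the sharp version of the study's
"same predictors" stability finding. The random scenario attenuates
true signals (classical measurement-error bias) and can flip borderline
variables; the comparison reports significance patterns and Jaccard
overlaps rather than asserting a fixed outcome.

## Synthetic data

The vessel generator produces straight or gently curved tubes
(base radius 1.5 mm, wall offset 0.5 mm, 72-point rings, 0.5 mm
spacing) with Gaussian-bump stenoses defined on area so "severity 0.5"
means exactly half the base area at the throat. The cohort generator
plants effects only on age (+0.01 per year) and baseline plaque burden
(−0.011 per %) against noise sd 0.15, with all other variables
log-normal null draws; with zero planted effects the univariate screen
rejects at the nominal 5% rate (calibration tested over 200 replicate
cohorts). A single global seed fans out into per-component child seeds
via `SeedSequence`.

What the generators do *not* emulate: branching coronary trees,
non-circular (eccentric) lumens, imaging noise and reconstruction
artefacts, correlated biohumoral panels, and longitudinal follow-up
structure. Passing tests therefore demonstrate the correctness and
internal consistency of the propagation machinery under controlled
conditions, not the clinical accuracy of any index on real CTCA data.

## Problem sizes

Default study sizes — 20 vessels × 3 models, 61 stations each, 5-day to
10-day growth horizons, 200-patient cohorts, 200 calibration
replicates — were chosen as the smallest sizes at which every
qualitative contract is comfortably resolved; the full pipeline runs in
well under a minute on one core.

## Known limitations

* The 1-D flow model has no secondary flow, recirculation or
  non-Newtonian rheology; shear is ring-averaged, so per-point shear
  "clouds" are emulated by broadcasting the station value.
* The wall model has no radial diffusion gradient, no wall mechanics,
  and its absolute outputs are arbitrary units.
* The healthy-reference definition (95th-percentile radius) is a
  convention; heavily diseased vessels with no healthy stretch will
  understate the reference and hence overstate SmartFFR.
* Bland–Altman CIs assume approximate normality of differences.
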
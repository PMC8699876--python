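# plaqueprop

Propagation of geometric reconstruction error through coronary
hemodynamics, SmartFFR and plaque-growth simulation.

Non-invasive CT coronary angiography lets coronary arteries be
reconstructed in 3-D and fed into computational models: wall shear
stress fields, fractional-flow-reserve surrogates, plaque-growth
simulators and, downstream, prognostic regressions. But segmentation
and reconstruction carry a known area error (~5%), and laboratory
biohumoral measurements carry an analytical error (up to ~13%). This
package is for modellers and methodologists who want to measure how
such input errors propagate level by level:

1. **Geometry** — vessels as lumen/outer-wall stacks of 72-point
   contours, 0.5 mm apart; every contour is scaled in-plane about its
   centroid so its area changes by exactly 1 ± e (overestimated /
   underestimated models).
2. **Hemodynamics** — a reduced-order model on the effective radius
   r(z) = sqrt(A/π): shear stress τ = 4μQ/(πr³), pressure drop from the
   Poiseuille gradient plus a Young-type separation loss at each
   stenosis throat. A uniform area error f shifts shear by exactly
   f^(−3/2).
3. **SmartFFR** — Pd/Pa over a 0–4 mL/s flow ramp, monotone-cubic
   resampled to 100 points; SmartFFR = AUC / AUC of a constant-radius
   healthy reference, with the 0.80 ± 0.03 grey zone.
4. **Plaque growth** — Kedem–Katchalsky endothelial influx with
   shear-dependent permeability P(τ) = P0(1 + a/(1 + bτ)), a
   ten-species wall cascade (LDL → oxLDL → macrophages → foam cells →
   cytokines → synthetic SMCs → collagen) and geometry feedback.
5. **Statistics** — paired comparisons, Bland–Altman limits
   mean ± 1.96σ with CIs, relative errors of summary statistics, and
   the quadrature uncertainty chain u = sqrt(σ² + u²_prev).
6. **Prognosis** — cohort regressions of plaque progression under
   analytical-error scenarios (none / ×1.13 / uniform [0.87, 1.13]),
   with significance-set stability comparison.

Everything runs on synthetic vessels and cohorts generated in-package
(`plaqueprop.synthetic`); bundled reference tables from a published
20-patient reconstruction-error study (`plaqueprop.datasets`) anchor
the statistics layer. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

```python
from plaqueprop.synthetic import VesselRecipe, StenosisSpec, generate_vessel
from plaqueprop.geometry import make_error_models
from plaqueprop.hemodynamics import axial_profile, compute_ess
from plaqueprop.smartffr import compute_smartffr
from plaqueprop.growth import run_growth, GrowthParams
from plaqueprop.stats import (PairedComparison, paired_stats,
                              relative_error_summary, propagate_uncertainty)

recipe = VesselRecipe(length=30.0, base_radius=1.5,
                      stenoses=(StenosisSpec(center=15.0, length=10.0, severity=0.6),),
                      seed=0, case_id="demo")
original, over, under = make_error_models(generate_vessel(recipe), error=0.05)

tau = {m.perturbation_tag: compute_ess(axial_profile(m)).tau
       for m in (original, over, under)}
re = relative_error_summary(
    (tau["original"].min(), tau["original"].max(), tau["original"].mean()),
    (tau["underestimated"].min(), tau["underestimated"].max(), tau["underestimated"].mean()))
mean, sd = paired_stats(PairedComparison(tau["original"], tau["underestimated"]))
print(f"relative error (min/max/mean): {re.re_min:+.2f}% / {re.re_max:+.2f}% / {re.re_mean:+.2f}%")
print(f"paired shear difference: {mean:.4f} +/- {sd:.4f} Pa")
print(f"chained uncertainty:     {propagate_uncertainty(sd, 0.09):.4f}")
for m in (over, original, under):
    r = compute_smartffr(m)
    print(f"SmartFFR {m.perturbation_tag:<14} {r.smartffr:.4f}  ({r.classification})")
for m in (over, original, under):
    g = run_growth(m, params=GrowthParams(t_end=10.0))
    print(f"plaque volume {m.perturbation_tag:<14} {g.final_total_plaque_volume:.3f} a.u.")
```

prints

```
relative error (min/max/mean): +8.00% / +8.00% / +8.00%
paired shear difference: -0.1499 +/- 0.0840 Pa
chained uncertainty:     0.1231
SmartFFR overestimated  0.9817  (healthy)
SmartFFR original       0.9798  (healthy)
SmartFFR underestimated 0.9776  (healthy)
plaque volume overestimated  10.786 a.u.
plaque volume original       11.205 a.u.
plaque volume underestimated 11.666 a.u.
```

Reading the numbers: undersizing every contour area by 5% raises shear
by exactly 0.95^(−3/2) − 1 = +8.00% everywhere (the closed-form
propagation law of the reduced-order model); the paired shear
difference (original − perturbed) is negative with its spread chained
in quadrature onto the 0.09 reconstruction-level uncertainty; SmartFFR
moves by ~0.002 per direction without leaving the healthy class — the
diagnostic index is robust to this error size; and the plaque-growth
level inherits the ordering underestimated > original > overestimated,
because a smaller lumen raises the wall's surface-to-volume ratio and
with it species accumulation.

The same chain is available from the shell:

```sh
plaqueprop generate --severity 0.6 --out vessel.csv
plaqueprop perturb --vessel vessel.csv --direction under --out under.csv
plaqueprop ess --vessel under.csv --report ess.csv
plaqueprop smartffr --vessel under.csv --report ffr.csv
plaqueprop grow --vessel under.csv --days 10 --report growth.csv
plaqueprop pipeline --seed 1 --out run/     # all stages, 3 vessels, manifest
```

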
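# twostep-imrt

Geometry-driven generation of adaptable prostate IMRT plans, MU-preserving
adaptation of those plans to the anatomy of the day, and quantitative plan
evaluation — exercisable end-to-end on a built-in horseshoe phantom and a
deformable synthetic prostate case.

## The problem

Prostate IMRT is planned once, on a planning CT, but delivered over ~33
fractions during which the prostate moves and deforms with rectum and
bladder filling. The standard image-guided response — a rigid couch shift
("isocenter relocation") — restores the target position but not its shape,
so either coverage or rectum sparing degrades. Full re-planning per
fraction is too slow and forces complete dosimetric re-verification.

**2-Step segmentation** builds IMRT plans out of apertures with explicit
geometric roles, per gantry angle and per target (PTV and Boost in a
simultaneous-integrated-boost prescription):

* **S0** — conformal to the target's beam's-eye-view (BEV) projection;
* **S1** — the target opening with the organ-at-risk (rectum) shadow
  removed, split into a left and a right one-sided aperture;
* **S2** — narrow strips adjacent to the OAR shadow edges that compensate
  the target underdosage S1 causes.

On concentric geometry (target outer radius R_PTV, OAR radius R_OAR, gap g;
normalized ρ_OAR = R_OAR/R_PTV, γ = g/R_PTV) the rotational dose of the
S1 aperture is D(ρ) = 1 − (2/π)·arcsin(min(1, ρ_OAR/ρ)) and the S2 strip of
normalized width β adds ω·(2/π)·[arcsin(min(1,(ρ_OAR+β)/ρ)) −
arcsin(min(1, ρ_OAR/ρ))]. The optimal (ω, β) minimizes
f² = σ_D² + (D̄ − D₀)² over the target annulus; the product
β\* = ω_opt·β_opt depends only weakly on γ and is tabulated over
(γ, ρ_OAR) with a 4th-order polynomial fit per γ node.

Because every segment has a geometric meaning, a plan can be **adapted
without changing monitor units**: after the clinical isocenter relocation,

1. regenerate the 2-Step segments on the geometry of the day and transfer
   each MU from its structural counterpart (same angle, step type, target,
   sidedness) in the planning geometry;
2. rescale each S2 strip width per leaf pair by
   β_CT2 = β_CT1 · β\*(γ_CT2, ρ_CT2) / β\*(γ_CT1, ρ_CT1), with β\* taken
   from the fixed-ω optimum (the weight cannot change when MUs are frozen);
3. replay the leaf shifts that inverse fine-tuning had introduced on the
   planning geometry, mapping leaf pairs by their normalized position
   within the target's (possibly changed) vertical BEV extent.

Plans are scored with DVH metrics (D_mean, D_x%, absolute rectum volumes
inside the 50/80/95% isodoses of 76.2 Gy) and the quality score **S_D**,
the sum of all violations of the required dose ranges in Gy (0 for a plan
meeting every requirement). Cohorts are compared with exact one-tailed
Wilcoxon signed-rank tests.

Dose is computed with an idealized exposure-fraction engine (unit primary
fluence, parallel beams, a discrete set of coplanar gantry angles), the
setting in which the S1/S2 closed forms hold; see `docs/methods.md` for
what this does and does not represent.

## Worked example

Adapt a phantom plan to a geometry of the day in which the OAR radius
shrinks by Δρ = 0.05 at constant gap (the target grows inward):

```python
import numpy as np
from twostep_imrt import (PhantomSpec, generate_quasimodo,
                          build_beta_star_table, DVH, DoseEngine)
from twostep_imrt.adaptation import make_native_plan, adapt_plan
from twostep_imrt.finetune import Objective

d0 = 60.0
ct1, ct2 = generate_quasimodo(PhantomSpec(n_slices=8), delta_rho=0.05)
table = build_beta_star_table()
objectives = [
    Objective("PTV", "min_dose", 0.98 * d0, weight=100.0),
    Objective("PTV", "max_dose", 1.03 * d0, weight=30.0),
    Objective("Rectum", "max_dose", 0.6 * d0, weight=10.0),
    Objective("Body", "max_dose", 1.05 * d0, weight=0.1),
]
native = make_native_plan(ct1, table, {"PTV": d0}, objectives=objectives)
result = adapt_plan(native, ct2, table)

engine = DoseEngine(ct2)
mask = engine.mask("PTV")
for label, plan in [("relocated", result.relocated),
                    ("adapted", result.adapted)]:
    d = engine.compute(plan, calibration=native.calibration).dose[mask]
    dvh = DVH("PTV", np.sort(d)[::-1], 1.0)
    print(f"{label:9s}  MU {plan.total_mu:6.1f}   "
          f"D95 {dvh.d_at(95):5.2f} Gy   D99 {dvh.d_at(99):5.2f} Gy   "
          f"f2 {np.mean((d - d0) ** 2):5.2f} Gy^2")
```

prints

```
relocated  MU  175.6   D95 54.67 Gy   D99 49.55 Gy   f2  6.61 Gy^2
adapted    MU  175.6   D95 57.85 Gy   D99 56.99 Gy   f2  2.73 Gy^2
```

The relocated-only plan underdoses the inward-grown target (D99 drops to
49.6 Gy of the prescribed 60 Gy); the three adaptation steps restore
coverage and homogeneity (D99 57.0 Gy, target f² from 6.6 to 2.7 Gy²)
with exactly the same total MU.

A command-line interface wraps the pipeline for shell use:

```
twostep phantom --delta-rho 0.05 --out work/
twostep table --out work/beta_table.json
twostep plan --structures work/ct1.json --table work/beta_table.json --out work/native.json
twostep adapt --native work/native.json --ct1 work/ct1.json --ct2 work/ct2.json \
              --table work/beta_table.json --out work/adapted
twostep eval --plan work/adapted/adapted_plan.json --structures work/ct2.json
twostep repro-tables
```

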
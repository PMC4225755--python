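# Methods

This note records the models, numerical choices, and limitations behind
`twostep_imrt`, in the order the pipeline runs.

## Geometry representation

Structures of interest (SOIs) are closed polygons on a common axial slice
grid (`StructureSet`), with the patient axis along z and "posterior" fixed
as −y. The gantry rotates coplanarly in the axial plane; angle 0° projects
onto the x-axis, and a point (x, y) relative to the isocenter projects to
u = dx·cosφ + dy·sinφ on the BEV axis. The projection is **parallel** —
the analytic rotation model underlying the S2 width rules is a
parallel-beam model, and divergence at prostate depths changes projected
widths by only a few percent. MLC leaf pairs tile z in 4 mm steps anchored
at the isocenter; a slice belongs to the pair whose z-range contains its
center, and a pair spanning several 2.5 mm slices averages their measured
quantities.

### Generators

* **Horseshoe phantom.** An annular horseshoe target (outer radius 60 mm,
  opening 60° posteriorly) around a cylindrical OAR (24 mm) with a 6 mm
  gap, inside a 300×200 mm elliptical body. These dimensions are
  *non-canonical*: the published phantom's data sheet is not reproduced
  here, so defaults were chosen once to give the characteristic
  almost-enclosed target and are fully configurable. The geometry-of-day
  variant reduces the normalized OAR radius by Δρ (default of interest
  0.05, the typical inter-fraction scale) while the target inner edge
  follows inward at constant normalized gap γ.
* **Synthetic prostate.** The CTV (prostate + seminal-vesicle base) is an
  ellipsoid-like stack of ellipses (≈46 cm³) with a posterior rectum tube;
  PTV and Boost are *derived* via the margin rules (10 mm, 7 mm posterior;
  5 mm with rectum excluded), so deformations propagate consistently. A
  deformation record pushes the prostate rigidly, scales the rectum
  radius, and shrinks the CTV until the derived Boost volume ratio matches
  a requested value (bisection to 0.3%): the bundled regimes are ≈5%
  (typical) and 25% Boost shrink (the hardest case the method is exposed
  to). Per-slice radius noise is drawn from the case seed and shared by
  both CTs, so a zero deformation yields bit-identical geometry pairs.
  What the generator does **not** emulate: rectum folding, bladder
  filling, seminal-vesicle articulation, CT noise, or contouring
  variability — passing tests show the adaptation machinery behaves
  correctly under controlled deformations, not that it handles every
  clinical anatomy.

### Margins

Margin expansion is per-slice 2D Minkowski dilation with a convex kernel
(circular anteriorly/laterally, elliptically blended down to the posterior
margin toward −y), plus cross-slice extension by the margin rounded to
whole slices. This is a tractable stand-in for full 3D dilation at the
native 2.5 mm slice resolution; the in-plane boundary is exact to the
kernel discretization (72 vertices, < 0.2 mm radial error at 10 mm).

### Normalized layer geometry

Per leaf pair and gantry angle, R_PTV and R_OAR are the projection
half-widths of target and OAR on the BEV axis; the gap g is the
edge-to-edge separation of the two polygons in the layer. When the OAR
overlaps the target material (a rectum bulging into the PTV) the gap is
reported *signed* (negative penetration depth) and the caller decides;
the β* lookup clamps γ to its domain. When a pair sees no OAR, ρ_OAR = 0
is returned with γ = NaN and an explicit flag.

## Dose engine

Dose is an **exposure fraction**: each voxel receives, per segment, the
segment MU times an indicator that its BEV projection lies inside the open
leaf interval — unit primary fluence, no attenuation, scatter, penumbra,
or output factors. This is precisely the idealization in which the
blocked-rotation closed forms and the f² optimum are derived, which makes
the engine the right instrument for testing the *adaptation logic*; it is
not a clinical dose calculation, and absolute OAR doses it reports are
optimistic. A rotation is approximated by 36 equispaced coplanar angles by
default (the discrete engine converges to the closed form as the beam
count grows; at 360 beams the radial profile agrees to 0.2% RMS).

A single calibration factor (Gy per MU·exposure) is fixed **once per
plan** so that the reference target's mean dose equals its prescription
(Boost when present). All plans derived from a native plan — relocated
baseline, adaptation steps — are evaluated with the *native* calibration,
mirroring a fixed machine output. One visible consequence: the engine
delivers nearly uniform target dose, so the Boost mean sits at the 74 Gy
prescription rather than at the ≈76 Gy ICRU-style mean of clinical plans,
and the protocol's `Boost Dmean ∈ [75.4, 77.0]` requirement contributes a
structural ~1.4 Gy to every synthetic S_D score. Comparisons between plan
groups are unaffected.

DVHs are held as the sorted voxel-dose sample (membership by
point-in-polygon at voxel centers, in-plane sampling at the structure
set's stated resolution, 2 mm default for the synthetic cases). D_x% is an
inverse cumulative lookup with linear interpolation between the volume
fraction centers (i + ½)/n; this rule is fixed here and may differ from
commercial systems at the ~0.1 Gy level. V_p% counts voxels at or above
p%·(reference dose); the reference defaults to 76.2 Gy so that V_95%
corresponds to the 72.4 Gy isodose.

## The radial model and the β* table

For the concentric model, f² = σ_D² + (D̄ − D₀)² is integrated over the
target annulus ρ ∈ [ρ_OAR + γ, 1] with area weight 2πρ dρ on a 1501-node
trapezoid grid; D₀ is the unblocked-rotation target mean, i.e. 1 in
normalized units. Because f² = E[(D − D₀)²], the optimal ω for fixed β is
the closed-form least-squares weight, leaving a 1D search over β (200-node
scan + bounded refinement, deterministic).

A structural property of the idealized model worth knowing: for narrow
strips the S2 dose profile scales with the *product* ω·β, so the joint
optimum is a flat ridge drifting toward arbitrarily narrow, heavy strips.
The search is therefore bounded (ω ∈ [0.2, 3], β up to 1 − ρ_OAR), which
both regularizes the optimum and matches what a deliverable aperture can
be; along the ridge ω·β ≡ β* is the identifiable quantity, and it is β*
that the method consumes.

The table covers ρ_OAR ∈ [0.05, 0.6] (12 nodes) × γ ∈ {0, 0.1, 0.2, 0.3}
and stores **two modes**: the free optimum (used at generation time with
the ω = 1 emission rule, strip width β*·R_PTV) and the fixed-ω (ω = 1)
optimum used by MU-preserving adaptation, where the weight cannot move.
Each mode gets a degree-4 polynomial in ρ_OAR per γ node, anchored through
the origin (β*(γ, 0) = 0), with linear interpolation across γ;
out-of-domain queries (tiny target slivers can measure ρ_OAR > 1) clamp to
the boundary with a warning. The measured fit residual is ≈9% at the
worst node — driven by ridge-selection kinks in the free mode — and is
stored in the table; the table is flagged when the residual exceeds 5%.
The measured γ-spread of β* is ≤ 20% (free) / ≤ 15% (fixed), the
quantitative content of "weakly γ-dependent" here.

## Fine-tuning (COV stage)

The composite objective value is a weighted sum of volume-normalized
quadratic DVH-point penalties (min-dose, max-dose, and dose-volume
objectives; for a max-DVH objective the voxels between the dose level and
the current dose at the allowed volume fraction are penalized). The
inverse optimizer of the clinical workflow is *not* reproduced — only its
interface is: a weight stage (projected gradient descent with
backtracking, 25 iterations, MUs ≥ 0, COV non-increasing by construction)
and a greedy leaf stage (single ±2 mm leaf moves accepted only on COV
decrease) that **records every accepted shift**. The record, not the
optimizer, is what adaptation needs. Segment count is frozen through
fine-tuning, MU and leaf updates are strictly separated, and the weight
stage freezes the plan calibration so the objective landscape does not
move under it. SOIs larger than 40 000 voxels (the body outline) enter the
COV model through a deterministic stride subsample; penalties are
volume-normalized, so this only reduces variance-free resolution, and it
bounds the contribution-matrix memory.

## Adaptation

Isocenter relocation rasterizes both target unions on a 1 mm in-plane /
native-slice grid, takes all integer-shift overlaps from one FFT
cross-correlation (rounded back to exact voxel counts), and maximizes
overlap within ±10 mm of the centroid shift; ties break to the smallest
shift norm, then lexicographically. The z component is quantized to whole
slices, since contours cannot be resampled between slices.

Step 1 regenerates S0/S1/S2 on the geometry of the day about the relocated
isocenter and copies MUs by structural key (angle, step type, target,
side). A key mismatch — the geometry change produced a different segment
inventory — is a **hard error** listing the offending keys; silently
redistributing MUs would break the method's premise. S2 widths are carried
over from the planning geometry (pair-mapped through the vertical
extents, anchored at the day's block edges) so that step 2's rescaling by
the fixed-ω β* ratio implements the width-update rule starting from
β_CT1. Step 3 replays the recorded leaf shifts with nearest-pair mapping
at equal normalized vertical position; re-validated apertures may close a
pair, never invert it. Steps 2 and 3 touch only geometry, so total MU is
conserved *exactly*, and the result object asserts it.

Adapting to an unchanged geometry is a verified fixed point: the adapted
dose grid is bit-identical to the native plan's, and a purely rigid
translation is recovered exactly. A guard estimates the
"native-equivalent" MU (the rescaling that would restore the reference
target mean on the day geometry); if it deviates by more than 10% the
adaptation proceeds but warns prominently — at that scale (≈25% volume
change) MU preservation is known to sacrifice either coverage or sparing.

On the mildly deformed synthetic prostate case the relocated baseline can
*outscore* the adapted plan on coverage while losing on rectum sparing:
the synthetic deformation is largely rigid, so relocation absorbs most of
it and the old, larger apertures over-cover the shrunken target. This is
expected behaviour of conformal MU-preserving adaptation under an
idealized engine, not a defect; the phantom pair, whose change is purely
non-rigid, shows the canonical relocated-underdose → step-1-overdose →
restored-homogeneity sequence.

## Evaluation and statistics

S_D sums one-sided violations of required dose ranges (defaults: Boost
D_mean 76.2 Gy ± 1%, D_99% > 70, D_95% 74 ± 2%, D_1% < 80; PTV−Boost
D_99% > 56, D_95% 60.1 ± 2%; all overridable via config). An achieved
value of `None` marks a metric not reported for a plan and is skipped; a
missing metric is an error. The score is 1-Lipschitz in each achieved
value.

The one-tailed Wilcoxon signed-rank test drops zero differences, midranks
ties, and reports two p-values: the **exact** tail probability of the
positive rank sum (dynamic program over doubled ranks — identical to full
sign-assignment enumeration, which the tests verify up to n = 10 — and
primary everywhere in this package) and the Gaussian approximation with
tie-corrected variance, reported because published cohort p-values are
typically of that flavour. The two can differ visibly at n = 10; neither
is forced onto the other.

The bundled ten-case cohort dataset ships with one caveat recorded here:
in the fully worked small-change case, the relocated column's printed
per-row violations round one entry down (56 − 48.3 = 7.7 printed as 7.6),
so the recomputed net S_D is 19.2 against a printed 19.1; the recomputed
value is reported as-is.

## Problem sizes

Default synthetic problem sizes — 8–28 slices of 2.5 mm, 2 mm in-plane
dose sampling, 36 beams, a 12×4 β* grid — were chosen as the smallest
sizes at which the discrete engine is comfortably inside its convergence
regime (the 360-beam, 1 mm convergence check runs separately); all are
configurable upward.

## Known limitations

* No attenuation, scatter, penumbra/tongue-and-groove, or deliverability
  constraints; OAR doses are optimistic and absolute Gy values are not
  clinically meaningful.
* Parallel projection; divergence is not modelled.
* One OAR per target; interacting S2 strips from multiple OARs are out of
  scope.
* MU-modifying adaptation (the escape hatch for large geometry changes)
  is not implemented; the guard only warns.
* DICOM-RT import/export is deliberately excluded; all formats are the
  documented JSON/CSV.
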
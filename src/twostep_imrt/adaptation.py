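"""MU-preserving 2-Step plan adaptation to the geometry of the day.

On top of the clinical baseline — rigid isocenter relocation for maximal
target overlap — three steps adapt a 2-Step plan from the planning
geometry CT1 to the geometry of the day CT2 without changing any monitor
units:

1. fresh 2-Step segment generation on CT2 at the relocated isocenter,
   with the MUs transferred segment-to-segment from CT1 by structural
   key (gantry angle, step type, target, sidedness);
2. adaptation of every S2 strip width by the ratio of the fixed-omega
   beta* values of the two geometries,
   beta_CT2 = beta_CT1 * beta*(gamma_CT2, rho_CT2) / beta*(gamma_CT1, rho_CT1),
   leaving MUs untouched (omega_CT2 = omega_CT1);
3. replay of the recorded fine-tuning leaf shifts, mapping leaf pairs by
   their normalized position within the target's changed BEV vertical
   extent.

The result carries the relocated-only baseline, all intermediate plans,
and an MU ledger asserting exact MU conservation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.signal import fftconvolve
from shapely.ops import unary_union

from .dose import DoseEngine, Plan, Segment, default_beams
from .finetune import LeafShiftRecord
from .geometry import (BODY, MLCSpec, NormalizedGeometry, StructureSet,
                       project_to_bev)
from .twostep import (BetaStarTable, generate_plan, measure_geometry_map)

logger = logging.getLogger(__name__)


class AdaptationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# native plan bundle
# ---------------------------------------------------------------------------


@dataclass
class NativePlan:
    """Everything the adaptation needs from the planning geometry: the
    structure set, the fine-tuned plan, the pre-fine-tune apertures, the
    leaf-shift record, and the frozen dose calibration (Gy per
    MU-exposure)."""

    ss: StructureSet
    plan: Plan                       # fine-tuned (delivered) plan
    plan_pre: Plan                   # pre-fine-tune apertures, same MUs
    record: LeafShiftRecord
    calibration: float
    targets: tuple[str, ...] = ("PTV",)
    oar: str = "Rectum"
    mlc: MLCSpec = field(default_factory=MLCSpec)


@dataclass
class AdaptationResult:
    shift: tuple[float, float, float]
    relocated: Plan                  # CT1 plan delivered at the relocated iso
    regenerated: Plan                # step 1: fresh segments, MUs transferred
    width_adapted: Plan              # step 2: Eq.-style S2 width scaling
    adapted: Plan                    # step 3: fine-tuning imitation
    iso2: tuple[float, float, float]
    mu_native: float
    mu_adapted: float
    geo1: dict[tuple[float, str, int], NormalizedGeometry]
    geo2: dict[tuple[float, str, int], NormalizedGeometry]
    beta_ratio: dict[tuple, dict[int, float]]
    mu_warning: str | None = None

    def mu_conserved(self) -> bool:
        return self.mu_adapted == self.mu_native


# ---------------------------------------------------------------------------
# isocenter relocation
# ---------------------------------------------------------------------------


def _rasterize_targets(ss: StructureSet, targets, xs, ys) -> np.ndarray:
    zs = ss.slice_zs(BODY)
    XX, YY = np.meshgrid(xs, ys)
    m = np.zeros((len(zs), len(ys), len(xs)), dtype=float)
    for iz, z in enumerate(zs):
        geoms = [ss.union_at(t, z) for t in targets]
        geoms = [g for g in geoms if g is not None and not g.is_empty]
        if not geoms:
            continue
        geom = unary_union(geoms)
        m[iz] = shapely.contains_xy(geom, XX.ravel(), YY.ravel()).reshape(XX.shape)
    return m


def relocate_isocenter(ct1: StructureSet, ct2: StructureSet,
                       targets: tuple[str, ...] = ("PTV",),
                       search_mm: float = 10.0,
                       grid_mm: float = 1.0) -> tuple[float, float, float]:
    """Rigid couch shift maximizing the summed target-overlap volume.

    Both target unions are rasterized on a common grid (``grid_mm``
    in-plane, the slice grid along z); the overlap of every integer-grid
    shift is obtained by FFT cross-correlation and the maximum within
    ``search_mm`` of the centroid shift is returned.  Ties break to the
    smallest shift norm, then lexicographically.  The z component is
    quantized to whole slices (contours cannot be resampled between
    slices).
    """
    for t in targets:
        if not ct1.structures.get(t) or not ct2.structures.get(t):
            raise AdaptationError(f"target {t!r} empty in one of the geometries")
    lo_x = min(c.points[:, 0].min() for s in (ct1, ct2)
               for t in targets for c in s.contours(t)) - search_mm - 2
    hi_x = max(c.points[:, 0].max() for s in (ct1, ct2)
               for t in targets for c in s.contours(t)) + search_mm + 2
    lo_y = min(c.points[:, 1].min() for s in (ct1, ct2)
               for t in targets for c in s.contours(t)) - search_mm - 2
    hi_y = max(c.points[:, 1].max() for s in (ct1, ct2)
               for t in targets for c in s.contours(t)) + search_mm + 2
    xs = np.arange(lo_x, hi_x, grid_mm)
    ys = np.arange(lo_y, hi_y, grid_mm)
    m1 = _rasterize_targets(ct1, targets, xs, ys)
    m2 = _rasterize_targets(ct2, targets, xs, ys)
    # the two slice grids may be offset; shifts below are in each array's
    # own z indexing, so the grid-origin offset is added back at the end
    z_off = ct2.slice_zs(BODY)[0] - ct1.slice_zs(BODY)[0]

    # full cross-correlation: index s corresponds to shifting m1 by
    # (s - (n-1)) grid cells and overlapping with m2
    corr = fftconvolve(m2, m1[::-1, ::-1, ::-1], mode="full")
    corr = np.rint(corr).astype(np.int64)

    dz_cells = np.arange(corr.shape[0]) - (m1.shape[0] - 1)
    dy_cells = np.arange(corr.shape[1]) - (m1.shape[1] - 1)
    dx_cells = np.arange(corr.shape[2]) - (m1.shape[2] - 1)
    sz = ct1.slice_thickness

    # centroid alignment defines the search window center
    def centroid(m):
        idx = np.argwhere(m > 0)
        return idx.mean(axis=0)
    c_shift = centroid(m2) - centroid(m1)   # in cells (z, y, x)

    best = None
    zs_keep = np.abs(dz_cells * sz - c_shift[0] * sz) <= search_mm + 1e-9
    ys_keep = np.abs(dy_cells * grid_mm - c_shift[1] * grid_mm) <= search_mm + 1e-9
    xs_keep = np.abs(dx_cells * grid_mm - c_shift[2] * grid_mm) <= search_mm + 1e-9
    for iz in np.flatnonzero(zs_keep):
        for iy in np.flatnonzero(ys_keep):
            for ix in np.flatnonzero(xs_keep):
                ov = corr[iz, iy, ix]
                shift = (dx_cells[ix] * grid_mm, dy_cells[iy] * grid_mm,
                         dz_cells[iz] * sz + z_off)
                norm = shift[0] ** 2 + shift[1] ** 2 + shift[2] ** 2
                cand = (-ov, norm, shift)
                if best is None or cand < best:
                    best = cand
    assert best is not None
    return best[2]


# ---------------------------------------------------------------------------
# step 1: regeneration with MU transfer
# ---------------------------------------------------------------------------


def _segments_by_key(plan: Plan) -> dict[tuple, Segment]:
    by_key: dict[tuple, Segment] = {}
    for s in plan.segments:
        if s.key in by_key:
            raise AdaptationError(f"duplicate segment key {s.key}")
        by_key[s.key] = s
    return by_key


def _map_pair(k2: int, ext1: tuple[int, int], ext2: tuple[int, int]) -> int:
    """CT2 leaf pair -> CT1 leaf pair at the same normalized position
    within the target's BEV vertical extent (nearest-pair rounding)."""
    lo1, hi1 = ext1
    lo2, hi2 = ext2
    if hi2 == lo2:
        return lo1
    frac = (k2 - lo2) / (hi2 - lo2)
    return int(round(lo1 + frac * (hi1 - lo1)))


def _pair_width_map(seg: Segment) -> dict[int, float]:
    return {k: hi - lo for k, (lo, hi) in seg.leaves.items()}


def regenerate_with_mu_transfer(native: NativePlan, ct2: StructureSet,
                                shift: tuple[float, float, float],
                                table: BetaStarTable,
                                ) -> tuple[Plan, dict, dict]:
    """Step 1: fresh S0/S1/S2 generation on CT2 at the relocated
    isocenter, MUs copied from the CT1 plan by structural key.

    S2 strip widths are carried over from the CT1 pre-fine-tune apertures
    (pair-mapped through the vertical extents), anchored at the CT2 block
    edges; step 2 then rescales them by the beta* ratio, which together
    realizes the width-adaptation rule starting from beta_CT1.  A key
    mismatch between the two segment sets is a hard error listing the
    offending keys — MUs are never silently redistributed.

    Returns the plan plus the per-(angle, target, pair) normalized
    geometries of CT1 and CT2 used later for the width ratio.
    """
    iso2 = tuple(np.add(native.ss.isocenter, shift))
    plan2 = generate_plan(
        ct2, table, native.plan.prescriptions, targets=native.targets,
        oar=native.oar, beams=native.plan.beams or default_beams(),
        mlc=native.mlc, iso=iso2, fractions=native.plan.fractions)

    by_key1 = _segments_by_key(native.plan_pre)
    by_key2 = _segments_by_key(plan2)
    missing_in_2 = sorted(set(by_key1) - set(by_key2))
    missing_in_1 = sorted(set(by_key2) - set(by_key1))
    if missing_in_2 or missing_in_1:
        raise AdaptationError(
            "segment sets of the two geometries do not match; "
            f"CT1-only keys: {missing_in_2}; CT2-only keys: {missing_in_1}. "
            "The geometry change is too large for keyed MU transfer.")

    geo1: dict[tuple, NormalizedGeometry] = {}
    geo2: dict[tuple, NormalizedGeometry] = {}
    for angle in plan2.beams:
        for target in native.targets:
            bev1 = project_to_bev(native.ss, angle, mlc=native.mlc)
            bev2 = project_to_bev(ct2, angle, mlc=native.mlc, iso=iso2)
            ks1 = [k for k in bev1.pairs if bev1.intervals(k, target)]
            ks2 = [k for k in bev2.pairs if bev2.intervals(k, target)]
            for k, g in measure_geometry_map(
                    native.ss, angle, ks1, target, native.oar,
                    mlc=native.mlc).items():
                geo1[(round(angle, 6), target, k)] = g
            for k, g in measure_geometry_map(
                    ct2, angle, ks2, target, native.oar,
                    mlc=native.mlc, iso=iso2).items():
                geo2[(round(angle, 6), target, k)] = g

    # transfer MUs and S2 widths
    for key, seg2 in by_key2.items():
        seg1 = by_key1[key]
        seg2.mu = seg1.mu
        if seg2.step_type != "S2":
            continue
        w1 = _pair_width_map(seg1)
        ext1 = (min(seg1.leaves), max(seg1.leaves)) if seg1.leaves else None
        ext2 = (min(seg2.leaves), max(seg2.leaves)) if seg2.leaves else None
        for k in list(seg2.leaves):
            if ext1 is None:
                break
            k1 = _map_pair(k, ext1, ext2)
            if k1 not in w1:
                k1 = min(w1, key=lambda kk: abs(kk - k1))
            lo, hi = seg2.leaves[k]
            w = w1[k1]
            if seg2.side == "L":       # anchored at its right edge (block left)
                seg2.leaves[k] = (hi - w, hi)
            else:                      # anchored at its left edge (block right)
                seg2.leaves[k] = (lo, lo + w)

    total1 = native.plan_pre.total_mu
    total2 = plan2.total_mu
    if not math.isclose(total1, total2, rel_tol=0, abs_tol=1e-9):
        raise AdaptationError("MU transfer failed to conserve total MU")
    return plan2, geo1, geo2


# ---------------------------------------------------------------------------
# step 2: S2 width adaptation
# ---------------------------------------------------------------------------


def adapt_s2_widths(plan: Plan,
                    geo1: dict[tuple, NormalizedGeometry],
                    geo2: dict[tuple, NormalizedGeometry],
                    table: BetaStarTable,
                    clip: dict[tuple, dict[int, tuple[float, float]]] | None = None,
                    ) -> tuple[Plan, dict]:
    """Step 2: rescale every S2 strip width by the fixed-omega beta* ratio
    of the day geometry to the planning geometry; MUs are untouched.

    The strip stays anchored at its OAR-shadow edge and is clipped to the
    target opening of the day (``clip[(angle, target)][pair]``) when
    given.  Out-of-domain geometries are clamped by the table lookup.
    """
    out = plan.copy()
    ratios: dict[tuple, dict[int, float]] = {}
    for seg in out.segments:
        if seg.step_type != "S2":
            continue
        ratios[seg.key] = {}
        for k in list(seg.leaves):
            gk = (round(seg.gantry_angle, 6), seg.target, k)
            g1, g2 = geo1.get(gk), geo2.get(gk)
            if g1 is None or g2 is None or not (g1.oar_present and g2.oar_present):
                ratio = 1.0
            else:
                b1 = table.lookup(max(0.0, g1.gamma), g1.rho_oar, mode="fixed")
                b2 = table.lookup(max(0.0, g2.gamma), g2.rho_oar, mode="fixed")
                ratio = b2 / b1 if b1 > 0 else 1.0
            ratios[seg.key][k] = ratio
            lo, hi = seg.leaves[k]
            w = (hi - lo) * ratio
            if seg.side == "L":
                lo = hi - w
            else:
                hi = lo + w
            if clip is not None:
                tgt = clip.get((round(seg.gantry_angle, 6), seg.target), {}).get(k)
                if tgt is not None:
                    lo, hi = max(lo, tgt[0]), min(hi, tgt[1])
            if hi > lo:
                seg.leaves[k] = (lo, hi)
            else:
                del seg.leaves[k]
    return out, ratios


# ---------------------------------------------------------------------------
# step 3: fine-tuning imitation
# ---------------------------------------------------------------------------


def imitate_finetuning(plan: Plan, record: LeafShiftRecord,
                       ct2_extents: dict[str, tuple[int, int]],
                       mlc: MLCSpec | None = None) -> Plan:
    """Step 3: re-apply the recorded CT1 leaf shifts to the CT2 segments.

    Each CT2 leaf pair maps to the CT1 pair at the same normalized
    position within the target's BEV vertical extent; the recorded (left,
    right) displacements are added and the aperture re-validated (pairs
    that would invert are closed, positions clipped to the field).  CT2
    pairs without a CT1 counterpart get zero shift (logged).
    """
    mlc = mlc or MLCSpec()
    out = plan.copy()
    half = mlc.field_half_width_mm
    for seg in out.segments:
        per = record.shifts.get(seg.key)
        if per is None:
            continue
        ext1 = record.target_extents.get(seg.target)
        ext2 = ct2_extents.get(seg.target, ext1)
        for k in sorted(seg.leaves):
            k1 = _map_pair(k, ext1, ext2) if ext1 and ext2 else k
            dl, dr = per.get(k1, (0.0, 0.0))
            lo, hi = seg.leaves[k]
            lo = min(max(lo + dl, -half), half)
            hi = min(max(hi + dr, -half), half)
            if hi > lo:
                seg.leaves[k] = (lo, hi)
            else:
                logger.debug("imitation closed pair %d of %s", k, seg.key)
                del seg.leaves[k]
    return out


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------


def adapt_plan(native: NativePlan, ct2: StructureSet, table: BetaStarTable,
               mu_guard: float = 0.10) -> AdaptationResult:
    """Run the full adaptation: relocate, regenerate with MU transfer,
    adapt S2 widths, imitate fine-tuning.

    The relocated-only baseline (the CT1 plan delivered at the relocated
    isocenter) is included for comparison.  Total MU is conserved exactly
    by construction; the result records the ledger.  When the
    native-equivalent MU estimate for CT2 deviates from the CT1 MUs by
    more than ``mu_guard`` the adaptation still proceeds but a prominent
    warning is attached: at that scale of geometry change MU-preserving
    adaptation is known to compromise either coverage or sparing.
    """
    present = [t for t in native.targets if ct2.structures.get(t)]
    if len(present) != len(native.targets):
        raise AdaptationError("CT2 is missing target structures")
    shift = relocate_isocenter(native.ss, ct2, targets=native.targets)
    iso2 = tuple(np.add(native.ss.isocenter, shift))

    regenerated, geo1, geo2 = regenerate_with_mu_transfer(
        native, ct2, shift, table)

    clip: dict[tuple, dict[int, tuple[float, float]]] = {}
    ct2_extents: dict[str, tuple[int, int]] = {}
    for angle in regenerated.beams:
        bev2 = project_to_bev(ct2, angle, mlc=native.mlc, iso=iso2)
        for target in native.targets:
            clip[(round(angle, 6), target)] = {
                k: bev2.hull(k, target) for k in bev2.pairs
                if bev2.intervals(k, target)}
            ext = bev2.target_extent(target)
            if ext is not None:
                cur = ct2_extents.get(target)
                ct2_extents[target] = (
                    ext if cur is None
                    else (min(cur[0], ext[0]), max(cur[1], ext[1])))

    width_adapted, ratios = adapt_s2_widths(regenerated, geo1, geo2, table,
                                            clip=clip)
    adapted = imitate_finetuning(width_adapted, native.record, ct2_extents,
                                 mlc=native.mlc)
    relocated = native.plan.copy()

    mu_native = native.plan.total_mu
    mu_adapted = adapted.total_mu
    if mu_adapted != mu_native:  # exact by construction
        raise AdaptationError(
            f"MU ledger mismatch: native {mu_native} vs adapted {mu_adapted}")

    # native-equivalent MU estimate: the rescaling that would restore the
    # reference-target mean to prescription on CT2
    warning = None
    engine2 = DoseEngine(ct2, mlc=native.mlc, iso=iso2)
    ref = "Boost" if "Boost" in native.plan.prescriptions else native.targets[0]
    raw = engine2.raw_exposure(adapted)
    mean = float(raw[engine2.mask(ref)].mean()) * native.calibration
    if mean > 0:
        mu_ratio = native.plan.prescriptions[ref] / mean
        if abs(mu_ratio - 1.0) > mu_guard:
            warning = (
                f"native-equivalent MU estimate differs by "
                f"{100 * abs(mu_ratio - 1):.0f}% (> {100 * mu_guard:.0f}%): the "
                "geometry change is at or beyond the limit of MU-preserving "
                "adaptation; either target coverage or OAR sparing may be "
                "compromised")
            warnings.warn(warning, stacklevel=2)
            logger.warning("%s", warning)

    return AdaptationResult(
        shift=shift, relocated=relocated, regenerated=regenerated,
        width_adapted=width_adapted, adapted=adapted, iso2=iso2,
        mu_native=mu_native, mu_adapted=mu_adapted,
        geo1=geo1, geo2=geo2, beta_ratio=ratios, mu_warning=warning)


def make_native_plan(ss: StructureSet, table: BetaStarTable,
                     prescriptions: dict[str, float],
                     targets: tuple[str, ...] = ("PTV",),
                     oar: str = "Rectum",
                     objectives=None,
                     beams: list[float] | None = None,
                     mlc: MLCSpec | None = None,
                     weight_iterations: int = 25,
                     leaf_iterations: int = 1,
                     leaf_step_mm: float = 2.0,
                     fractions: int = 33) -> NativePlan:
    """Full planning pipeline on one geometry: 2-Step generation, MU
    weight optimization, greedy leaf fine-tuning with shift recording,
    and dose calibration (reference-target mean = prescription)."""
    from .finetune import default_objectives, finetune_leaves, optimize_weights

    mlc = mlc or MLCSpec()
    if objectives is None:
        d_ptv = prescriptions.get("PTV", next(iter(prescriptions.values())))
        d_boost = prescriptions.get("Boost", d_ptv)
        objectives = [o for o in default_objectives(d_ptv, d_boost)
                      if o.structure in ss.structures
                      or o.structure in ("PTV-Boost",)]
    engine = DoseEngine(ss, mlc=mlc)
    plan0 = generate_plan(ss, table, prescriptions, targets=targets, oar=oar,
                          beams=beams, mlc=mlc, fractions=fractions)
    plan_w = optimize_weights(plan0, ss, objectives,
                              iterations=weight_iterations, engine=engine)
    calibration = engine.calibration_for(plan_w)
    if leaf_iterations > 0:
        plan_ft, record = finetune_leaves(
            plan_w, ss, objectives, step_mm=leaf_step_mm,
            iterations=leaf_iterations, engine=engine, calibration=calibration)
    else:
        from .finetune import LeafShiftRecord as _LSR
        plan_ft, record = plan_w.copy(), _LSR()
        for seg in plan_ft.segments:
            record.shifts.setdefault(seg.key, {})
        for t in targets:
            ks = [k for s in plan_ft.segments if s.target == t for k in s.leaves]
            if ks:
                record.target_extents[t] = (min(ks), max(ks))
    calibration = engine.calibration_for(plan_ft)
    return NativePlan(ss, plan_ft, plan_w, record, calibration,
                      targets=targets, oar=oar, mlc=mlc)


__all__ = [
    "AdaptationError", "AdaptationResult", "NativePlan", "adapt_plan",
    "make_native_plan",
    "adapt_s2_widths", "imitate_finetuning", "regenerate_with_mu_transfer",
    "relocate_isocenter",
]
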
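"""Segment fine-tuning against a composite objective value (COV).

The COV is the sum of weighted, volume-normalized quadratic penalties on
DVH points.  Two monotone-descent stages operate on a plan:

* :func:`optimize_weights` adjusts segment MUs only (projected gradient
  descent, a fixed number of iterations, default 25);
* :func:`finetune_leaves` greedily moves single leaves and accepts a move
  only when the COV decreases, recording every accepted shift in a
  :class:`LeafShiftRecord`.

The shift record is what MU-preserving adaptation replays on the geometry
of the day; the split between the stages mirrors the separation the
adaptation relies on (weight optimization never touches leaves, leaf
fine-tuning never touches MUs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dose import DoseEngine, DoseGrid, Plan, Segment

logger = logging.getLogger(__name__)


class FinetuneError(ValueError):
    pass


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

OBJECTIVE_KINDS = ("min_dose", "max_dose", "max_dvh", "min_dvh")


@dataclass(frozen=True)
class Objective:
    """One DVH-point objective.

    ``min_dose`` / ``max_dose`` penalize every voxel below/above
    ``dose_gy``.  ``max_dvh`` requires V(>= dose_gy) <= volume_fraction:
    the excess voxels (those between dose_gy and the current dose at the
    allowed volume fraction) are penalized by their dose above dose_gy;
    ``min_dvh`` is the mirror image.
    """

    structure: str
    kind: str
    dose_gy: float
    weight: float = 1.0
    volume_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise FinetuneError(f"unknown objective kind {self.kind!r}")
        if self.weight <= 0 or self.dose_gy <= 0:
            raise FinetuneError("objective weight and dose must be > 0")
        if self.kind.endswith("dvh") and not (
                self.volume_fraction is not None and 0 < self.volume_fraction < 1):
            raise FinetuneError("dose-volume objectives need volume_fraction in (0,1)")


ObjectiveSpec = list[Objective]


def default_objectives(d_ptv: float, d_boost: float,
                       reference_dose: float | None = None) -> ObjectiveSpec:
    """Objective template for the SIB prostate protocol.

    Four PTV objectives (two near the minimum, two near the maximum),
    three for the Boost, four shaping the rectum DVH, and a low-weight cap
    on the surrounding healthy tissue; weights span 0.1-100.
    """
    ref = reference_dose or d_boost
    return [
        Objective("PTV", "min_dose", 0.99 * d_ptv, weight=100.0),
        Objective("PTV", "min_dose", 0.96 * d_ptv, weight=50.0),
        Objective("PTV", "max_dvh", 1.05 * d_boost, weight=10.0,
                  volume_fraction=0.05),
        Objective("PTV", "max_dose", 1.10 * d_boost, weight=20.0),
        Objective("Boost", "min_dose", 0.98 * d_boost, weight=100.0),
        Objective("Boost", "min_dose", 0.95 * d_boost, weight=50.0),
        Objective("Boost", "max_dose", 1.04 * d_boost, weight=20.0),
        Objective("Rectum", "max_dvh", 0.50 * ref, weight=2.0, volume_fraction=0.40),
        Objective("Rectum", "max_dvh", 0.65 * ref, weight=3.0, volume_fraction=0.20),
        Objective("Rectum", "max_dvh", 0.80 * ref, weight=5.0, volume_fraction=0.08),
        Objective("Rectum", "max_dose", 0.95 * ref, weight=5.0),
        Objective("Body", "max_dose", 1.08 * d_boost, weight=0.1),
    ]


def _penalties(doses: np.ndarray, obj: Objective) -> np.ndarray:
    if obj.kind == "min_dose":
        return np.maximum(0.0, obj.dose_gy - doses)
    if obj.kind == "max_dose":
        return np.maximum(0.0, doses - obj.dose_gy)
    n = doses.size
    srt = np.sort(doses)[::-1]
    i = min(int(math.floor(obj.volume_fraction * n)), n - 1)
    d_v = srt[i]  # current dose at the allowed volume fraction
    pen = np.zeros(n)
    if obj.kind == "max_dvh":
        if d_v > obj.dose_gy:
            sel = (doses > obj.dose_gy) & (doses <= d_v)
            pen[sel] = doses[sel] - obj.dose_gy
    else:  # min_dvh
        if d_v < obj.dose_gy:
            sel = (doses < obj.dose_gy) & (doses >= d_v)
            pen[sel] = obj.dose_gy - doses[sel]
    return pen


def _cov_from_soi_doses(soi_doses: dict[str, np.ndarray],
                        objectives: ObjectiveSpec) -> float:
    total = 0.0
    for obj in objectives:
        d = soi_doses[obj.structure]
        p = _penalties(d, obj)
        total += obj.weight * float(p @ p) / d.size
    return total


def cov(dose: DoseGrid, ss_or_engine, objectives: ObjectiveSpec) -> float:
    """Composite objective value of a dose distribution.

    COV = sum over objectives of weight * mean over SOI voxels of the
    squared penalty.  Raises if an objective's SOI is absent.
    """
    engine = (ss_or_engine if isinstance(ss_or_engine, DoseEngine)
              else DoseEngine(ss_or_engine))
    soi_doses = {}
    for obj in objectives:
        if obj.structure in soi_doses:
            continue
        m = engine.mask(obj.structure)
        if not m.any():
            raise FinetuneError(f"objective SOI {obj.structure!r} absent or empty")
        soi_doses[obj.structure] = dose.dose[m]
    return _cov_from_soi_doses(soi_doses, objectives)


# ---------------------------------------------------------------------------
# shift record
# ---------------------------------------------------------------------------


@dataclass
class LeafShiftRecord:
    """Leaf shifts introduced by fine-tuning, per segment and leaf pair.

    ``shifts[key][pair] = (d_left, d_right)`` in mm (fine-tuned minus
    pre-fine-tune position).  ``target_extents[target]`` stores the
    target's BEV vertical extent (first, last leaf-pair index) at
    recording time, needed to replay the shifts on a geometry whose
    vertical extent changed.
    """

    shifts: dict[tuple, dict[int, tuple[float, float]]] = field(default_factory=dict)
    target_extents: dict[str, tuple[int, int]] = field(default_factory=dict)

    def shift_for(self, key: tuple, pair: int) -> tuple[float, float]:
        return self.shifts.get(key, {}).get(pair, (0.0, 0.0))

    def is_zero(self) -> bool:
        return all(dl == 0.0 and dr == 0.0
                   for per in self.shifts.values() for dl, dr in per.values())


def apply_shift_record(plan: Plan, record: LeafShiftRecord) -> Plan:
    """Replay recorded shifts 1:1 (identity pair mapping)."""
    out = plan.copy()
    for seg in out.segments:
        per = record.shifts.get(seg.key)
        if not per:
            continue
        for k in list(seg.leaves):
            dl, dr = per.get(k, (0.0, 0.0))
            lo, hi = seg.leaves[k]
            lo, hi = lo + dl, hi + dr
            if hi > lo:
                seg.leaves[k] = (lo, hi)
            else:
                del seg.leaves[k]
    return out


# ---------------------------------------------------------------------------
# weight optimization
# ---------------------------------------------------------------------------


class _CovModel:
    """COV as a function of the MU vector for fixed apertures.

    Precomputes each segment's calibrated dose contribution on the union
    of objective SOI voxels; the calibration is frozen from the input plan
    so the objective landscape does not move under the optimizer.
    """

    #: very large SOIs (the body outline) are represented by a
    #: deterministic stride subsample; penalties are volume-normalized,
    #: so the COV estimate is unbiased and the memory stays bounded
    MAX_SOI_VOXELS = 40_000

    def __init__(self, plan: Plan, engine: DoseEngine,
                 objectives: ObjectiveSpec, calibration: float | None = None):
        self.objectives = objectives
        self.engine = engine
        self.sois = sorted({o.structure for o in objectives})
        masks = {}
        for s in self.sois:
            m = engine.mask(s)
            if not m.any():
                raise FinetuneError(f"objective SOI {s!r} absent or empty")
            n = int(m.sum())
            if n > self.MAX_SOI_VOXELS:
                keep = np.flatnonzero(m.ravel())[::n // self.MAX_SOI_VOXELS + 1]
                m = np.zeros_like(m).ravel()
                m[keep] = True
                m = m.reshape(engine.mask(s).shape)
            masks[s] = m
        if calibration is None:
            calibration = engine.calibration_for(plan)
        self.calibration = calibration
        union = np.zeros_like(next(iter(masks.values())))
        for m in masks.values():
            union |= m
        self.union = union
        self.index = {}
        flat = np.flatnonzero(union.ravel())
        pos = {v: i for i, v in enumerate(flat)}
        for s, m in masks.items():
            self.index[s] = np.array(
                [pos[v] for v in np.flatnonzero(m.ravel())], dtype=int)
        # contribution matrix: (n_segments, n_union_voxels), Gy per unit MU
        rows = []
        for seg in plan.segments:
            unit = seg.copy()
            unit.mu = 1.0
            rows.append(engine.segment_exposure(unit)[union].astype(np.float32)
                        * np.float32(calibration))
        self.M = np.asarray(rows, dtype=np.float32)

    def doses(self, mu: np.ndarray) -> np.ndarray:
        return mu @ self.M

    def cov(self, mu: np.ndarray) -> float:
        d = self.doses(mu)
        soi = {s: d[idx] for s, idx in self.index.items()}
        return _cov_from_soi_doses(soi, self.objectives)

    def grad(self, mu: np.ndarray) -> np.ndarray:
        d = self.doses(mu)
        gd = np.zeros_like(d)
        for obj in self.objectives:
            idx = self.index[obj.structure]
            dv = d[idx]
            p = _penalties(dv, obj)
            sign = -1.0 if obj.kind in ("min_dose", "min_dvh") else 1.0
            gd[idx] += obj.weight * 2.0 * sign * p / dv.size
        return self.M @ gd


def optimize_weights(plan: Plan, ss, objectives: ObjectiveSpec,
                     iterations: int = 25, engine: DoseEngine | None = None,
                     calibration: float | None = None) -> Plan:
    """Optimize segment MUs by projected gradient descent.

    Leaf positions are never touched.  Each iteration takes the steepest
    descent direction with backtracking so the COV sequence is
    non-increasing; MUs are projected to >= 0.  Deterministic.  If the
    starting gradient vanishes the input plan is returned unchanged.
    """
    engine = engine or DoseEngine(ss)
    model = _CovModel(plan, engine, objectives, calibration)
    mu = np.array([s.mu for s in plan.segments], dtype=float)
    f = model.cov(mu)
    g = model.grad(mu)
    if not np.any(g):
        logger.warning("weight optimization: zero gradient at start; no-op")
        return plan.copy()
    step = 0.5 * (np.max(mu) + 1.0) / (np.max(np.abs(g)) + 1e-300)
    for _ in range(iterations):
        g = model.grad(mu)
        gnorm = np.max(np.abs(g))
        if gnorm == 0.0 or f == 0.0:
            break
        improved = False
        s = step
        for _ in range(30):
            trial = np.maximum(0.0, mu - s * g)
            ft = model.cov(trial)
            if ft < f:
                mu, f, step, improved = trial, ft, s * 1.5, True
                break
            s *= 0.5
        if not improved:
            break
    out = plan.copy()
    for seg, m in zip(out.segments, mu):
        seg.mu = float(m)
    return out


# ---------------------------------------------------------------------------
# greedy leaf fine-tuning
# ---------------------------------------------------------------------------


def finetune_leaves(plan: Plan, ss, objectives: ObjectiveSpec,
                    step_mm: float = 2.0, iterations: int = 2,
                    engine: DoseEngine | None = None,
                    calibration: float | None = None,
                    ) -> tuple[Plan, LeafShiftRecord]:
    """Greedy single-leaf fine-tuning under fixed MUs.

    Sweeps segments, leaf pairs, and both leaves in a fixed order; a
    +-``step_mm`` move is accepted only when it lowers the COV, so
    COV(after) <= COV(before).  Every accepted net displacement is stored
    in the returned :class:`LeafShiftRecord` together with each target's
    BEV vertical extent.  ``iterations`` counts full sweeps; 0 returns the
    plan unchanged with an all-zero record.
    """
    if step_mm <= 0:
        raise FinetuneError("step_mm must be > 0")
    engine = engine or DoseEngine(ss)
    model = _CovModel(plan, engine, objectives, calibration)
    out = plan.copy()
    record = LeafShiftRecord()
    keys = [s.key for s in out.segments]
    if len(set(keys)) != len(keys):
        raise FinetuneError(
            "segments must have unique (angle, type, target, side) keys "
            "for the shift record to map one-to-one")
    for seg in out.segments:
        record.shifts.setdefault(seg.key, {})
        if seg.target not in record.target_extents:
            ks = [k for s in out.segments if s.target == seg.target
                  for k in s.leaves]
            record.target_extents[seg.target] = (min(ks), max(ks))

    mu = np.array([s.mu for s in out.segments], dtype=float)
    dose_union = model.doses(mu)
    f = _cov_from_soi_doses(
        {s: dose_union[idx] for s, idx in model.index.items()}, model.objectives)

    union = model.union
    cal = model.calibration

    def delta_exposure(seg: Segment, k: int, lo: float, hi: float) -> np.ndarray:
        """Calibrated dose on the union voxels of strip [lo, hi) of pair k."""
        if hi <= lo:
            return np.zeros(union.sum())
        probe = Segment(seg.gantry_angle, {k: (lo, hi)}, mu=seg.mu,
                        step_type=seg.step_type, target=seg.target, side=seg.side)
        return engine.segment_exposure(probe)[union] * cal

    for _ in range(iterations):
        accepted = 0
        for seg in out.segments:
            if seg.mu == 0.0:
                continue
            for k in sorted(seg.leaves):
                for which in (0, 1):       # left, right leaf
                    for sgn in (-1.0, 1.0):
                        lo, hi = seg.leaves[k]
                        d = sgn * step_mm
                        nlo, nhi = (lo + d, hi) if which == 0 else (lo, hi + d)
                        if nhi <= nlo:
                            continue
                        half = engine.mlc.field_half_width_mm
                        if nlo < -half or nhi > half:
                            continue
                        # dose delta: strip gained minus strip lost
                        if which == 0:
                            delta = (delta_exposure(seg, k, min(nlo, lo), max(nlo, lo))
                                     * (1.0 if nlo < lo else -1.0))
                        else:
                            delta = (delta_exposure(seg, k, min(hi, nhi), max(hi, nhi))
                                     * (1.0 if nhi > hi else -1.0))
                        trial = dose_union + delta
                        ft = _cov_from_soi_doses(
                            {s: trial[idx] for s, idx in model.index.items()},
                            model.objectives)
                        if ft < f - 1e-12:
                            seg.leaves[k] = (nlo, nhi)
                            dose_union, f = trial, ft
                            dl, dr = record.shifts[seg.key].get(k, (0.0, 0.0))
                            if which == 0:
                                dl += d
                            else:
                                dr += d
                            record.shifts[seg.key][k] = (dl, dr)
                            accepted += 1
        if accepted == 0:
            break
    logger.info("leaf fine-tuning: COV %.4g, %d sweeps requested", f, iterations)
    return out, record


__all__ = [
    "FinetuneError", "LeafShiftRecord", "Objective", "ObjectiveSpec",
    "apply_shift_record", "cov", "default_objectives", "finetune_leaves",
    "optimize_weights",
]
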
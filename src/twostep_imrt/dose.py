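"""Idealized exposure-fraction dose engine, DVHs, and DVH metrics.

The engine deposits, per voxel, the sum over segments of the segment MU
times an indicator that the voxel's parallel BEV projection at the
segment's gantry angle lies inside the segment's open leaf interval
(unit primary fluence, no attenuation or scatter).  A single calibration
factor (Gy per MU-exposure) converts the raw sum to Gy; by default it is
chosen once per plan so that the plan's reference-target mean dose equals
the prescription.

The closed-form continuous-rotation doses for an OAR-blocking aperture
(S1) and a narrow strip aperture (S2) on concentric geometry are provided
as the analytic limit the discrete engine converges to.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .geometry import BODY, MLCSpec, StructureSet

logger = logging.getLogger(__name__)


class DoseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# plan containers
# ---------------------------------------------------------------------------

STEP_TYPES = ("S0", "S1", "S2")


@dataclass
class Segment:
    """One MLC aperture at one gantry angle.

    ``leaves`` maps leaf-pair index -> open interval (left, right) in mm on
    the BEV u-axis; pairs absent from the dict are closed.  ``side``
    distinguishes the left/right one-sided apertures that S1/S2 emit when
    the OAR shadow splits the opening.
    """

    gantry_angle: float
    leaves: dict[int, tuple[float, float]]
    mu: float = 0.0
    step_type: str = "S0"
    target: str = "PTV"
    side: str | None = None  # "L", "R" or None

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise DoseError("segment MU must be >= 0")
        if self.step_type not in STEP_TYPES:
            raise DoseError(f"unknown step type {self.step_type!r}")
        for k, (lo, hi) in self.leaves.items():
            if hi < lo:
                raise DoseError(f"leaf pair {k}: left {lo} > right {hi}")

    @property
    def key(self) -> tuple[float, str, str, str | None]:
        """Structural identity used for MU transfer between geometries."""
        return (round(self.gantry_angle, 6), self.step_type, self.target, self.side)

    def copy(self) -> "Segment":
        return Segment(self.gantry_angle, dict(self.leaves), self.mu,
                       self.step_type, self.target, self.side)


@dataclass
class Plan:
    """A beam set with MLC segments and per-target prescriptions (total Gy)."""

    segments: list[Segment]
    prescriptions: dict[str, float]
    fractions: int = 33
    beams: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.beams:
            allowed = {round(b, 6) for b in self.beams}
            for s in self.segments:
                if round(s.gantry_angle, 6) not in allowed:
                    raise DoseError(
                        f"segment {s.key} at {s.gantry_angle} deg is not in the "
                        "configured beam set")

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu for s in self.segments))

    def copy(self) -> "Plan":
        return Plan([s.copy() for s in self.segments], dict(self.prescriptions),
                    self.fractions, list(self.beams))

    def shifted(self, shift: tuple[float, float, float],
                mlc: MLCSpec | None = None) -> "Plan":
        """Plan as delivered after a rigid isocenter relocation.

        A couch shift moves the patient; in patient coordinates the
        apertures translate with the isocenter: on the u-axis by the
        projection of the in-plane shift, along z by whole leaf pairs.
        Used only to evaluate the relocated-only baseline, where the
        caller supplies the relocated isocenter to the dose engine
        instead; this helper exists for explicit aperture translation.
        """
        mlc = mlc or MLCSpec()
        dk = int(round(shift[2] / mlc.leaf_width_mm))
        out = []
        for s in self.segments:
            phi = math.radians(s.gantry_angle)
            du = shift[0] * math.cos(phi) + shift[1] * math.sin(phi)
            leaves = {k + dk: (lo + du, hi + du) for k, (lo, hi) in s.leaves.items()}
            out.append(Segment(s.gantry_angle, leaves, s.mu, s.step_type,
                               s.target, s.side))
        return Plan(out, dict(self.prescriptions), self.fractions, list(self.beams))


def default_beams(n_angles: int = 36) -> list[float]:
    """Equispaced coplanar gantry angles approximating a rotation."""
    return [360.0 * i / n_angles for i in range(n_angles)]


# ---------------------------------------------------------------------------
# voxel grid and engine
# ---------------------------------------------------------------------------


@dataclass
class DoseGrid:
    """Voxel dose (Gy) on the structure set's grid, axes in mm."""

    dose: np.ndarray          # (nz, ny, nx)
    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray
    calibration: float        # Gy per MU-exposure

    @property
    def voxel_volume_cm3(self) -> float:
        dx = self.xs[1] - self.xs[0] if len(self.xs) > 1 else 1.0
        dy = self.ys[1] - self.ys[0] if len(self.ys) > 1 else 1.0
        dz = self.zs[1] - self.zs[0] if len(self.zs) > 1 else 1.0
        return float(dx * dy * dz) / 1000.0


class DoseEngine:
    """Caches the voxel grid, SOI masks, and per-angle projections of one
    structure set so many plans/segments can be evaluated cheaply."""

    def __init__(self, ss: StructureSet, mlc: MLCSpec | None = None,
                 iso: tuple[float, float, float] | None = None,
                 resolution: float | None = None):
        self.ss = ss
        self.mlc = mlc or MLCSpec()
        self.iso = iso if iso is not None else ss.isocenter
        res = resolution or ss.in_plane_resolution

        xs_min = min(c.points[:, 0].min() for c in ss.contours(BODY))
        xs_max = max(c.points[:, 0].max() for c in ss.contours(BODY))
        ys_min = min(c.points[:, 1].min() for c in ss.contours(BODY))
        ys_max = max(c.points[:, 1].max() for c in ss.contours(BODY))
        self.xs = np.arange(xs_min + res / 2, xs_max, res)
        self.ys = np.arange(ys_min + res / 2, ys_max, res)
        self.zs = np.asarray(ss.slice_zs(BODY), dtype=float)
        self._XX, self._YY = np.meshgrid(self.xs, self.ys)  # (ny, nx)
        self._u_cache: dict[float, np.ndarray] = {}
        self._mask_cache: dict[str, np.ndarray] = {}

        # slice index -> leaf pair index
        self._pair_of_slice = np.array(
            [self.mlc.pair_of_z(z, self.iso[2]) for z in self.zs], dtype=int)
        self._slices_of_pair: dict[int, np.ndarray] = {}
        for i, k in enumerate(self._pair_of_slice):
            self._slices_of_pair.setdefault(int(k), []).append(i)
        self._slices_of_pair = {
            k: np.asarray(v, dtype=int) for k, v in self._slices_of_pair.items()}

    # -- projections -------------------------------------------------------

    def _u(self, angle: float) -> np.ndarray:
        key = round(angle, 9)
        if key not in self._u_cache:
            phi = math.radians(angle)
            self._u_cache[key] = (
                (self._XX - self.iso[0]) * math.cos(phi)
                + (self._YY - self.iso[1]) * math.sin(phi))
        return self._u_cache[key]

    # -- SOI membership ----------------------------------------------------

    def mask(self, name: str) -> np.ndarray:
        """Boolean (nz, ny, nx) membership by point-in-polygon at centers.

        The derived SOI ``"PTV-Boost"`` (target shell outside the boost)
        is recognized as the set difference of the two masks.
        """
        if name not in self._mask_cache:
            if "-" in name and name not in self.ss.structures:
                a, b = name.split("-", 1)
                self._mask_cache[name] = self.mask(a.strip()) & ~self.mask(b.strip())
            else:
                m = np.zeros((len(self.zs), len(self.ys), len(self.xs)), dtype=bool)
                flat_x = self._XX.ravel()
                flat_y = self._YY.ravel()
                for iz, z in enumerate(self.zs):
                    geom = self.ss.union_at(name, z)
                    if geom is None or geom.is_empty:
                        continue
                    inside = shapely.contains_xy(geom, flat_x, flat_y)
                    m[iz] = inside.reshape(self._XX.shape)
                self._mask_cache[name] = m
        return self._mask_cache[name]

    # -- dose --------------------------------------------------------------

    def segment_exposure(self, seg: Segment) -> np.ndarray:
        """Raw (MU-weighted) exposure of one segment on the full grid."""
        out = np.zeros((len(self.zs), len(self.ys), len(self.xs)))
        if seg.mu == 0.0:
            return out
        u = self._u(seg.gantry_angle)
        for k, (lo, hi) in seg.leaves.items():
            idx = self._slices_of_pair.get(k)
            if idx is None or hi <= lo:
                continue
            m2d = (u >= lo) & (u <= hi)
            out[idx] += seg.mu * m2d
        return out

    def raw_exposure(self, plan: Plan) -> np.ndarray:
        out = np.zeros((len(self.zs), len(self.ys), len(self.xs)))
        for seg in plan.segments:
            out += self.segment_exposure(seg)
        return out

    def calibration_for(self, plan: Plan, reference_target: str | None = None,
                        raw: np.ndarray | None = None) -> float:
        """Gy per MU-exposure so the reference target mean equals its
        prescription.  Reference: Boost if prescribed, else the first
        prescription entry."""
        if reference_target is None:
            reference_target = ("Boost" if "Boost" in plan.prescriptions
                                else next(iter(plan.prescriptions)))
        raw = self.raw_exposure(plan) if raw is None else raw
        m = self.mask(reference_target)
        mean = float(raw[m].mean()) if m.any() else 0.0
        if mean <= 0:
            raise DoseError(
                f"cannot calibrate: zero mean exposure in {reference_target}")
        return plan.prescriptions[reference_target] / mean

    def compute(self, plan: Plan, calibration: float | None = None,
                reference_target: str | None = None) -> DoseGrid:
        raw = self.raw_exposure(plan)
        if calibration is None:
            calibration = self.calibration_for(plan, reference_target, raw=raw)
        return DoseGrid(raw * calibration, self.xs, self.ys, self.zs, calibration)


def compute_dose(plan: Plan, ss: StructureSet, mlc: MLCSpec | None = None,
                 calibration: float | None = None,
                 iso: tuple[float, float, float] | None = None) -> DoseGrid:
    """Convenience wrapper building a one-shot :class:`DoseEngine`."""
    return DoseEngine(ss, mlc=mlc, iso=iso).compute(plan, calibration=calibration)


# ---------------------------------------------------------------------------
# closed-form blocked-rotation doses (analytic limit of the engine)
# ---------------------------------------------------------------------------


def blocked_rotation_dose(rho, rho_oar: float):
    """Continuous-rotation dose of the OAR-blocking aperture (S1).

    A point at normalized radius rho on concentric geometry is exposed for
    the fraction of the rotation in which its projection falls outside the
    central block of half-width rho_oar:
    D(rho) = 1 - (2/pi) * arcsin(min(1, rho_oar/rho)).
    """
    rho = np.asarray(rho, dtype=float)
    if rho_oar < 0 or rho_oar >= 1:
        raise DoseError("rho_oar must be in [0, 1)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rho > 0, rho_oar / np.maximum(rho, 1e-300), np.inf)
    d = 1.0 - (2.0 / math.pi) * np.arcsin(np.minimum(1.0, ratio))
    d = np.where(rho == 0, 1.0 if rho_oar == 0 else 0.0, d)
    return d if d.shape else float(d)


def strip_rotation_dose(rho, rho_oar: float, beta: float):
    """Continuous-rotation dose of a strip aperture open on
    rho_oar <= |u| <= rho_oar + beta (the S2 compensation strip)."""
    rho = np.asarray(rho, dtype=float)
    if beta < 0:
        raise DoseError("beta must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / np.maximum(rho, 1e-300)
    hi = np.arcsin(np.minimum(1.0, (rho_oar + beta) * inv))
    lo = np.arcsin(np.minimum(1.0, rho_oar * inv))
    d = (2.0 / math.pi) * (hi - lo)
    d = np.where(rho == 0, 1.0 if rho_oar == 0 and beta > 0 else 0.0, d)
    return d if d.shape else float(d)


def radial_dose_closed_form(rho, rho_oar: float, beta) -> float | np.ndarray:
    """Radial dose of a single blocked rotation on concentric geometry.

    ``beta="full"`` gives the S1 (OAR-blocking) aperture; a numeric
    ``beta`` gives the narrow S2 strip of that normalized width.  The total
    two-step dose is ``D_S1 + omega * D_S2``.
    """
    if isinstance(beta, str):
        if beta != "full":
            raise DoseError('beta must be a number or "full"')
        return blocked_rotation_dose(rho, rho_oar)
    return strip_rotation_dose(rho, rho_oar, float(beta))


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------


@dataclass
class DVH:
    """Cumulative DVH of one SOI, held as the sorted voxel dose sample."""

    structure: str
    doses: np.ndarray          # voxel doses in Gy, sorted descending
    voxel_volume_cm3: float

    @classmethod
    def from_dose(cls, grid: DoseGrid, mask: np.ndarray, structure: str) -> "DVH":
        d = np.sort(grid.dose[mask].ravel())[::-1]
        if d.size == 0:
            raise DoseError(f"empty SOI {structure!r}: no voxels in mask")
        return cls(structure, d, grid.voxel_volume_cm3)

    @property
    def total_volume_cm3(self) -> float:
        return self.doses.size * self.voxel_volume_cm3

    def curve(self, n_bins: int = 256):
        """(dose_Gy, fractional volume >= dose, absolute cm^3) arrays."""
        axis = np.linspace(0.0, float(self.doses[0]) + 1e-9, n_bins)
        frac = np.searchsorted(-self.doses, -axis, side="right") / self.doses.size
        return axis, frac, frac * self.total_volume_cm3

    def d_at(self, x_percent: float) -> float:
        """D_x%: minimum dose received by the hottest x% of the volume.

        Inverse cumulative lookup with linear interpolation between the
        volume-fraction centers (i + 1/2)/n of the descending-sorted voxel
        sample.
        """
        if not 0.0 < x_percent <= 100.0:
            raise DoseError("x must be in (0, 100]")
        n = self.doses.size
        centers = (np.arange(n) + 0.5) / n
        return float(np.interp(x_percent / 100.0, centers, self.doses))

    def v_at(self, p_percent: float, reference_dose: float) -> float:
        """V_p%: absolute volume (cm^3) receiving >= p% of the reference."""
        if not 0.0 < p_percent <= 100.0:
            raise DoseError("p must be in (0, 100]")
        thr = p_percent / 100.0 * reference_dose
        return float((self.doses >= thr).sum() * self.voxel_volume_cm3)

    @property
    def mean(self) -> float:
        return float(self.doses.mean())


def dvh_metrics(dvh: DVH, d_points: tuple[float, ...] = (99.0, 95.0, 1.0),
                v_points: tuple[float, ...] = (),
                reference_dose: float | None = None) -> dict[str, float]:
    """The DVH statistics used in plan evaluation: D_mean, D_x% (Gy) and,
    when a reference dose is given, absolute V_p% (cm^3)."""
    out = {"Dmean": dvh.mean}
    for x in d_points:
        out[f"D{x:g}%"] = dvh.d_at(x)
    for p in v_points:
        if reference_dose is None:
            raise DoseError("V_p% metrics need a reference dose")
        out[f"V{p:g}%"] = dvh.v_at(p, reference_dose)
    return out


__all__ = [
    "DVH", "DoseEngine", "DoseError", "DoseGrid", "Plan", "Segment",
    "blocked_rotation_dose", "compute_dose", "default_beams", "dvh_metrics",
    "radial_dose_closed_form", "strip_rotation_dose",
]
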
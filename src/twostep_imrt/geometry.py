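"""Axial-slice structure geometry for 2-Step IMRT planning.

Structures of interest (SOIs) are represented as closed polygons on a common
axial slice grid.  The module provides

* generators for a QUASIMODO-like horseshoe phantom (planning geometry CT1
  and geometry-of-day CT2) and for a deformable synthetic prostate case,
* anisotropic margin expansion (CTV -> PTV / Boost),
* parallel-beam beam's-eye-view (BEV) projection onto the MLC leaf grid, and
* measurement of the normalized quantities rho_OAR and gamma that the
  2-Step segmentation rules consume.

Coordinate convention: the axial plane is (x, y) in mm, the patient axis is
z; "posterior" is the -y direction.  Gantry angle 0 deg projects onto the
x-axis and the BEV u-axis increases with patient x at 0 deg; for angle phi
(degrees) the projection of a point (x, y) relative to the isocenter is
u = dx*cos(phi) + dy*sin(phi).  The projection is parallel (no divergence).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

# canonical SOI names
CTV = "CTV"
PTV = "PTV"
BOOST = "Boost"
RECTUM = "Rectum"
BODY = "Body"

_AREA_EPS = 1e-6  # mm^2; polygons below this are discarded


class GeometryError(ValueError):
    """Raised when a structure or generator specification is invalid."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MLCSpec:
    """Multi-leaf collimator description.

    Leaf pairs run along the patient axis: pair ``k`` covers the z-range
    ``[iso_z + k*leaf_width, iso_z + (k+1)*leaf_width)`` at the isocenter
    plane.  ``field_half_width`` limits leaf travel on the BEV u-axis.
    """

    leaf_width_mm: float = 4.0
    field_half_width_mm: float = 200.0

    def pair_of_z(self, z: float, iso_z: float) -> int:
        return int(math.floor((z - iso_z) / self.leaf_width_mm))

    def pair_z_range(self, k: int, iso_z: float) -> tuple[float, float]:
        return (iso_z + k * self.leaf_width_mm, iso_z + (k + 1) * self.leaf_width_mm)


@dataclass
class Contour:
    """A closed polygon on one axial slice (vertices in mm)."""

    slice_z: float
    points: np.ndarray  # (n, 2) float array, not repeated at the end

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise GeometryError("a contour needs >= 3 (x, y) vertices")
        self.points = pts

    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def validate(self) -> None:
        poly = self.polygon()
        if not poly.is_valid:
            raise GeometryError(
                f"self-intersecting contour at z={self.slice_z:g} mm"
            )
        if poly.area <= _AREA_EPS:
            raise GeometryError(f"degenerate contour at z={self.slice_z:g} mm")

    @property
    def area(self) -> float:
        return self.polygon().area


@dataclass
class StructureSet:
    """All SOIs of one CT on a common axial slice grid."""

    structures: dict[str, list[Contour]]
    slice_thickness: float
    in_plane_resolution: float
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def names(self) -> list[str]:
        return list(self.structures)

    def contours(self, name: str) -> list[Contour]:
        try:
            return self.structures[name]
        except KeyError:
            raise GeometryError(f"structure {name!r} not in set") from None

    def slice_zs(self, name: str | None = None) -> list[float]:
        if name is not None:
            zs = {c.slice_z for c in self.contours(name)}
        else:
            zs = {c.slice_z for cs in self.structures.values() for c in cs}
        return sorted(zs)

    def polygons_at(self, name: str, z: float, tol: float = 1e-6):
        return [
            c.polygon() for c in self.structures.get(name, ())
            if abs(c.slice_z - z) <= tol
        ]

    def union_at(self, name: str, z: float):
        polys = self.polygons_at(name, z)
        if not polys:
            return None
        return unary_union(polys)

    def volume(self, name: str) -> float:
        """Structure volume in cm^3 (sum of slice areas x thickness)."""
        area = sum(c.area for c in self.contours(name))
        return area * self.slice_thickness / 1000.0

    def validate(self) -> None:
        for name, cs in self.structures.items():
            for c in cs:
                try:
                    c.validate()
                except GeometryError as exc:
                    raise GeometryError(f"{name}: {exc}") from None

    def shifted(self, shift: tuple[float, float, float]) -> "StructureSet":
        """Rigidly translated copy (contours and isocenter move together)."""
        sx, sy, sz = shift
        structs = {
            name: [
                Contour(c.slice_z + sz, c.points + np.array([sx, sy]))
                for c in cs
            ]
            for name, cs in self.structures.items()
        }
        iso = tuple(np.add(self.isocenter, shift))
        return StructureSet(structs, self.slice_thickness,
                            self.in_plane_resolution, iso)  # type: ignore[arg-type]


@dataclass(frozen=True)
class PhantomSpec:
    """Dimensions of the horseshoe phantom (all lengths in mm).

    The target is an annular horseshoe of outer radius ``r_ptv`` around a
    central cylindrical OAR of radius ``r_oar``, separated by the gap
    ``gap``; a wedge of ``opening_deg`` degrees (centered posteriorly) is
    removed so the OAR is almost, but not fully, enclosed.  The default
    dimensions are non-canonical: they are chosen to reproduce the
    qualitative geometry, not a published data sheet.
    """

    body_half_axes: tuple[float, float] = (150.0, 100.0)
    r_oar: float = 24.0
    r_ptv: float = 60.0
    gap: float = 6.0
    opening_deg: float = 60.0
    n_slices: int = 12
    slice_thickness: float = 2.5
    in_plane_resolution: float = 2.0

    def validate(self) -> None:
        for fname in ("r_oar", "r_ptv", "gap", "slice_thickness",
                      "in_plane_resolution"):
            if getattr(self, fname) <= 0 and fname != "gap":
                raise GeometryError(f"phantom spec: {fname} must be > 0")
        if self.gap < 0:
            raise GeometryError("phantom spec: gap must be >= 0")
        if self.r_oar + self.gap >= self.r_ptv:
            raise GeometryError(
                "phantom spec: r_oar + gap must be < r_ptv "
                f"({self.r_oar} + {self.gap} >= {self.r_ptv})"
            )
        if min(self.body_half_axes) <= self.r_ptv:
            raise GeometryError("phantom spec: body must enclose the target")
        if not 0 < self.opening_deg < 180:
            raise GeometryError("phantom spec: opening angle must be in (0, 180) deg")
        if self.n_slices < 1:
            raise GeometryError("phantom spec: n_slices must be >= 1")


@dataclass(frozen=True)
class NormalizedGeometry:
    """Scale-free layer geometry: rho_oar = R_OAR/R_PTV, gamma = g/R_PTV.

    ``gamma`` is reported signed: negative values mean the OAR overlaps the
    target material in that layer; the caller decides how to treat them
    (the beta* lookup clamps to its domain).  When the OAR is absent,
    ``rho_oar`` is 0 and ``gamma`` is NaN with ``oar_present`` False.
    """

    rho_oar: float
    gamma: float
    r_ptv: float
    oar_present: bool = True


@dataclass
class BEVProjection:
    """Per-leaf-pair 1D projections of every SOI at one gantry angle.

    ``pairs[k][name]`` is a sorted list of disjoint ``(u_lo, u_hi)``
    intervals in mm at the isocenter plane.
    """

    gantry_angle: float
    mlc: MLCSpec
    iso: tuple[float, float, float]
    pairs: dict[int, dict[str, list[tuple[float, float]]]]

    def intervals(self, k: int, name: str) -> list[tuple[float, float]]:
        return self.pairs.get(k, {}).get(name, [])

    def hull(self, k: int, name: str) -> tuple[float, float] | None:
        ivs = self.intervals(k, name)
        if not ivs:
            return None
        return (ivs[0][0], ivs[-1][1])

    def target_extent(self, name: str) -> tuple[int, int] | None:
        """First and last leaf-pair index with a non-empty projection."""
        ks = [k for k, sois in self.pairs.items() if sois.get(name)]
        if not ks:
            return None
        return (min(ks), max(ks))


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _slice_grid(n_slices: int, thickness: float, center_z: float = 0.0) -> np.ndarray:
    offsets = (np.arange(n_slices) - (n_slices - 1) / 2.0) * thickness
    return center_z + offsets


def _arc(radius: float, th0: float, th1: float, n: int,
         center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    th = np.linspace(th0, th1, n)
    return np.column_stack(
        (center[0] + radius * np.cos(th), center[1] + radius * np.sin(th))
    )


def _ellipse(a: float, b: float, center: tuple[float, float] = (0.0, 0.0),
             n: int = 128) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack((center[0] + a * np.cos(th), center[1] + b * np.sin(th)))


def _horseshoe(r_inner: float, r_outer: float, opening_deg: float,
               n_arc: int = 181) -> np.ndarray:
    """Annulus with a posterior wedge removed; opening centered on -y."""
    half = math.radians(opening_deg) / 2.0
    th0 = -math.pi / 2.0 + half           # one lip of the opening
    th1 = th0 + 2.0 * math.pi - 2.0 * half
    outer = _arc(r_outer, th0, th1, n_arc)
    inner = _arc(r_inner, th1, th0, n_arc)
    return np.vstack((outer, inner))


def _poly_contours(geom, z: float) -> list[Contour]:
    """Split a (Multi)Polygon into Contour records, dropping slivers."""
    if geom is None or geom.is_empty:
        return []
    parts = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    out = []
    for p in parts:
        if isinstance(p, Polygon) and p.area > _AREA_EPS:
            out.append(Contour(z, np.asarray(p.exterior.coords[:-1], dtype=float)))
    return out


# ---------------------------------------------------------------------------
# phantom generator
# ---------------------------------------------------------------------------


def generate_quasimodo(spec: PhantomSpec,
                       delta_rho: float = 0.0) -> tuple[StructureSet, StructureSet]:
    """Generate the horseshoe phantom pair (CT1, CT2).

    From CT1 to CT2 the OAR radius is reduced by ``delta_rho * r_ptv`` and
    the target inner edge follows inward so the normalized gap gamma stays
    constant: the target *gains* area on every slice.  ``delta_rho = 0``
    yields identical sets.  Isocenters coincide at the origin.
    """
    spec.validate()
    rho_oar = spec.r_oar / spec.r_ptv
    if not 0.0 <= delta_rho < rho_oar:
        raise GeometryError(
            f"delta_rho must be in [0, rho_oar={rho_oar:.3f}), got {delta_rho}"
        )

    def build(r_oar: float) -> StructureSet:
        zs = _slice_grid(spec.n_slices, spec.slice_thickness)
        body = _ellipse(*spec.body_half_axes, n=180)
        target = _horseshoe(r_oar + spec.gap, spec.r_ptv, spec.opening_deg)
        oar = _arc(r_oar, 0.0, 2.0 * math.pi * (1 - 1.0 / 180), 180)
        structs: dict[str, list[Contour]] = {PTV: [], CTV: [], RECTUM: [], BODY: []}
        for z in zs:
            structs[PTV].append(Contour(z, target.copy()))
            structs[CTV].append(Contour(z, target.copy()))
            structs[RECTUM].append(Contour(z, oar.copy()))
            structs[BODY].append(Contour(z, body.copy()))
        ss = StructureSet(structs, spec.slice_thickness, spec.in_plane_resolution)
        ss.validate()
        return ss

    ct1 = build(spec.r_oar)
    ct2 = build(spec.r_oar - delta_rho * spec.r_ptv)
    return ct1, ct2


def concentric_structure_set(r_ptv: float = 80.0, rho_oar: float = 0.3,
                             gamma: float = 0.1, n_slices: int = 2,
                             slice_thickness: float = 2.5,
                             in_plane_resolution: float = 1.0) -> StructureSet:
    """Rotationally symmetric test geometry: an annular target of outer
    radius ``r_ptv`` and inner radius ``(rho_oar + gamma) * r_ptv`` around
    a central circular OAR — the discrete counterpart of the concentric
    closed-form dose model (realized as a horseshoe with a negligible
    0.5 deg opening, since a slice contour is a single closed polygon)."""
    zs = _slice_grid(n_slices, slice_thickness)
    target = _horseshoe((rho_oar + gamma) * r_ptv, r_ptv, 0.5, n_arc=256)
    oar = _arc(rho_oar * r_ptv, 0.0, 2.0 * math.pi * (1 - 1.0 / 180), 180)
    body = _arc(1.3 * r_ptv, 0.0, 2.0 * math.pi * (1 - 1.0 / 180), 180)
    structs: dict[str, list[Contour]] = {
        PTV: [Contour(z, target.copy()) for z in zs],
        RECTUM: [Contour(z, oar.copy()) for z in zs],
        BODY: [Contour(z, body.copy()) for z in zs],
    }
    return StructureSet(structs, slice_thickness, in_plane_resolution)


# ---------------------------------------------------------------------------
# synthetic prostate generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeformationSpec:
    """Inter-fraction change applied between CT1 and CT2.

    ``boost_volume_ratio`` is the requested Boost volume ratio CT2/CT1
    (1.0 = no change, 0.75 = the hardest regime); the prostate (CTV) is
    scaled isotropically until the derived Boost hits it.  ``shift_mm``
    pushes the prostate rigidly (e.g. inferior/posterior displacement by
    bladder and rectum filling); ``rectum_radius_scale`` mimics changed
    rectum filling.  ``jitter_mm`` is the sigma of smooth per-slice radius
    noise applied to the *base* anatomy (shared by CT1 and CT2).
    """

    boost_volume_ratio: float = 1.0
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rectum_radius_scale: float = 1.0
    jitter_mm: float = 0.5


def small_deformation() -> DeformationSpec:
    """Roughly 5% target volume change - the typical inter-fraction regime."""
    return DeformationSpec(boost_volume_ratio=0.95, shift_mm=(0.0, -2.0, -2.0),
                           rectum_radius_scale=1.1)


def large_deformation() -> DeformationSpec:
    """25% Boost shrink - the hardest regime the adaptation is exposed to."""
    return DeformationSpec(boost_volume_ratio=0.75, shift_mm=(0.0, -4.0, -5.0),
                           rectum_radius_scale=1.3)


@dataclass(frozen=True)
class ProstateSpec:
    """Base anatomy of the synthetic prostate case (mm).

    The CTV (prostate + base of seminal vesicles) is an ellipsoid-like
    stack of ellipses; the rectum is a tube directly posterior to it; the
    body is an elliptic cylinder.  Sizes give a CTV of roughly 45 cm^3 and
    a Boost (CTV + 5 mm, rectum excluded) of roughly 80-90 cm^3, typical
    of intermediate-risk prostate cases.
    """

    ctv_half_axes: tuple[float, float, float] = (25.0, 20.0, 22.0)
    ctv_center: tuple[float, float] = (0.0, 12.0)
    rectum_center_y: float = -24.0
    rectum_radius: float = 13.0
    body_half_axes: tuple[float, float] = (170.0, 115.0)
    n_slices: int = 28
    slice_thickness: float = 2.5
    in_plane_resolution: float = 2.0


def generate_prostate_case(
    seed: int,
    deformation: DeformationSpec | None = None,
    spec: ProstateSpec | None = None,
    margins: "MarginSpec | None" = None,
) -> tuple[StructureSet, StructureSet]:
    """Build a deformable synthetic prostate pair (CT1, CT2).

    CT1 is the planning geometry; CT2 applies ``deformation``.  PTV and
    Boost are derived from the CTV with the clinical margin rules (10 mm,
    7 mm posteriorly, for the PTV; 5 mm with rectum excluded for the
    Boost), so a CTV change propagates consistently.  Reproducible: the
    same seed yields bit-identical sets.  Reports the volumetric change of
    each SOI at INFO level.
    """
    deformation = deformation or DeformationSpec()
    spec = spec or ProstateSpec()
    margins = margins or MarginSpec()
    rng = np.random.default_rng(seed)
    zs = _slice_grid(spec.n_slices, spec.slice_thickness)

    # smooth per-slice radius jitter shared by both CTs (base anatomy)
    jit = rng.normal(0.0, deformation.jitter_mm, size=len(zs))
    jit = np.convolve(jit, np.ones(3) / 3.0, mode="same")

    def build(ctv_scale: float, shift: tuple[float, float, float],
              rect_scale: float) -> StructureSet:
        a, b, c = spec.ctv_half_axes
        a, b, c = a * ctv_scale, b * ctv_scale, c * ctv_scale
        cx = spec.ctv_center[0] + shift[0]
        cy = spec.ctv_center[1] + shift[1]
        cz = shift[2]
        structs: dict[str, list[Contour]] = {CTV: [], RECTUM: [], BODY: []}
        for i, z in enumerate(zs):
            rel = (z - cz) / c
            if abs(rel) < 0.999:
                s = math.sqrt(1.0 - rel * rel)
                ra, rb = a * s + jit[i], b * s + jit[i]
                if min(ra, rb) > 2.0:
                    structs[CTV].append(
                        Contour(z, _ellipse(ra, rb, (cx, cy), n=96)))
            rr = spec.rectum_radius * rect_scale + 0.5 * jit[i]
            structs[RECTUM].append(
                Contour(z, _ellipse(rr, rr, (0.0, spec.rectum_center_y), n=72)))
            structs[BODY].append(Contour(z, _ellipse(*spec.body_half_axes, n=160)))
        ss = StructureSet(structs, spec.slice_thickness, spec.in_plane_resolution)
        _derive_prostate_targets(ss, margins)
        ss.validate()
        _check_inside_body(ss)
        return ss

    ct1 = build(1.0, (0.0, 0.0, 0.0), 1.0)

    ratio = deformation.boost_volume_ratio
    if ratio == 1.0 and deformation.shift_mm == (0.0, 0.0, 0.0) \
            and deformation.rectum_radius_scale == 1.0:
        return ct1, build(1.0, (0.0, 0.0, 0.0), 1.0)

    v1 = ct1.volume(BOOST)

    def boost_ratio(scale: float) -> float:
        ss = build(scale, deformation.shift_mm, deformation.rectum_radius_scale)
        return ss.volume(BOOST) / v1

    # bisect the CTV scale so the derived Boost hits the requested ratio
    lo, hi = 0.5, 1.3
    scale = ratio ** (1.0 / 3.0)  # ellipsoid guess
    for _ in range(20):
        r = boost_ratio(scale)
        if abs(r - ratio) < 0.003:
            break
        if r > ratio:
            hi = scale
        else:
            lo = scale
        scale = 0.5 * (lo + hi)
    ct2 = build(scale, deformation.shift_mm, deformation.rectum_radius_scale)

    for name in (CTV, PTV, BOOST, RECTUM):
        dv = ct2.volume(name) / ct1.volume(name) - 1.0
        logger.info("prostate case seed=%d: %s volume change %+.1f%%",
                    seed, name, 100.0 * dv)
    return ct1, ct2


def _derive_prostate_targets(ss: StructureSet, margins: "MarginSpec") -> None:
    zs = sorted({c.slice_z for c in ss.contours(BODY)})
    ss.structures[PTV] = expand_margin(
        ss.contours(CTV), zs, ss.slice_thickness,
        margins.ptv_mm, posterior_mm=margins.ptv_posterior_mm)
    ss.structures[BOOST] = expand_margin(
        ss.contours(CTV), zs, ss.slice_thickness, margins.boost_mm,
        forbidden=ss.contours(RECTUM))


def _check_inside_body(ss: StructureSet) -> None:
    for name in ss.names():
        if name == BODY:
            continue
        for c in ss.contours(name):
            body = ss.union_at(BODY, c.slice_z)
            if body is None or not body.buffer(1e-6).contains(c.polygon()):
                raise GeometryError(
                    f"{name} leaves the body outline at z={c.slice_z:g} mm; "
                    "reduce the deformation magnitude")


# ---------------------------------------------------------------------------
# margin expansion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarginSpec:
    """Clinical margin rules: CTV+10 mm (7 mm posterior) -> PTV;
    CTV+5 mm with rectum excluded -> Boost."""

    ptv_mm: float = 10.0
    ptv_posterior_mm: float = 7.0
    boost_mm: float = 5.0


def _structuring_element(margin: float, posterior: float, n: int = 72) -> Polygon:
    """Convex kernel: radius ``margin`` in the upper half-plane, elliptic
    blend down to ``posterior`` toward -y."""
    th = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    r = np.full(n, margin)
    lower = np.sin(th) < 0
    denom = np.hypot(posterior * np.cos(th[lower]), margin * np.sin(th[lower]))
    r[lower] = margin * posterior / np.maximum(denom, 1e-12)
    return Polygon(np.column_stack((r * np.cos(th), r * np.sin(th))))


def _minkowski_dilate(poly: Polygon, kernel: Polygon) -> Polygon | MultiPolygon:
    """Minkowski sum of a polygon with a convex kernel."""
    kpts = np.asarray(kernel.exterior.coords[:-1], dtype=float)
    verts = np.asarray(poly.exterior.coords, dtype=float)  # closed ring
    pieces = [poly]
    for i in range(len(verts) - 1):
        v0, v1 = verts[i], verts[i + 1]
        swept = np.vstack((kpts + v0, kpts + v1))
        pieces.append(Polygon(swept).convex_hull)
    return unary_union(pieces)


def expand_margin(
    base: list[Contour],
    slice_zs: list[float],
    slice_thickness: float,
    margin_mm: float,
    posterior_mm: float | None = None,
    z_mm: float | None = None,
    forbidden: list[Contour] | None = None,
) -> list[Contour]:
    """Expand a structure by per-direction margins.

    Per slice the polygons are dilated in 2D with an anisotropic convex
    kernel (``posterior_mm`` toward -y, ``margin_mm`` elsewhere); across
    slices the structure is extended by ``z_mm`` (default ``margin_mm``)
    rounded to whole slices.  When ``forbidden`` is given its area is
    removed from the result on every slice.  Slices where the result comes
    out empty are omitted (logged at DEBUG level).
    """
    if margin_mm < 0 or (posterior_mm is not None and posterior_mm < 0):
        raise GeometryError("margins must be >= 0")
    posterior = margin_mm if posterior_mm is None else posterior_mm
    z_margin = margin_mm if z_mm is None else z_mm
    n_ext = int(round(z_margin / slice_thickness))

    zs = sorted(slice_zs)
    by_z: dict[int, list] = {}
    for c in base:
        i = int(round(min(range(len(zs)), key=lambda j: abs(zs[j] - c.slice_z))))
        by_z.setdefault(i, []).append(c.polygon())

    # in-plane dilation once per occupied slice
    if margin_mm == 0.0 and posterior == 0.0:
        dilated = {i: unary_union(polys) for i, polys in by_z.items()}
    else:
        kernel = _structuring_element(margin_mm, max(posterior, 1e-9))
        dilated = {
            i: unary_union([_minkowski_dilate(p, kernel) for p in polys])
            for i, polys in by_z.items()
        }

    forb_by_z: dict[float, list] = {}
    for c in forbidden or []:
        forb_by_z.setdefault(round(c.slice_z, 6), []).append(c.polygon())

    out: list[Contour] = []
    for i, z in enumerate(zs):
        window = [dilated[j] for j in range(i - n_ext, i + n_ext + 1) if j in dilated]
        if not window:
            continue
        geom = unary_union(window)
        forb = forb_by_z.get(round(z, 6))
        if forb:
            geom = geom.difference(unary_union(forb))
        cs = _poly_contours(geom, z)
        if not cs:
            logger.debug("margin expansion empty at z=%g mm; slice omitted", z)
        out.extend(cs)
    return out


# ---------------------------------------------------------------------------
# BEV projection and normalized-geometry measurement
# ---------------------------------------------------------------------------


def _merge_intervals(ivs: list[tuple[float, float]],
                     tol: float = 1e-9) -> list[tuple[float, float]]:
    ivs = sorted(ivs)
    out: list[tuple[float, float]] = []
    for a, b in ivs:
        if out and a <= out[-1][1] + tol:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _project_poly(poly, cosφ: float, sinφ: float,
                  iso_xy: tuple[float, float]) -> list[tuple[float, float]]:
    parts = poly.geoms if isinstance(poly, MultiPolygon) else [poly]
    ivs = []
    for p in parts:
        xy = np.asarray(p.exterior.coords, dtype=float)
        u = (xy[:, 0] - iso_xy[0]) * cosφ + (xy[:, 1] - iso_xy[1]) * sinφ
        ivs.append((float(u.min()), float(u.max())))
    return ivs


def project_to_bev(
    ss: StructureSet,
    gantry_angle: float,
    mlc: MLCSpec | None = None,
    iso: tuple[float, float, float] | None = None,
) -> BEVProjection:
    """Parallel-beam projection of every SOI onto the MLC leaf grid.

    For each leaf pair (indexed along z) and each SOI the sorted disjoint
    intervals of the projection on the BEV u-axis are returned, in mm at
    the isocenter plane.  Slices are assigned to the leaf pair whose
    z-range contains the slice center.
    """
    mlc = mlc or MLCSpec()
    iso = iso if iso is not None else ss.isocenter
    phi = math.radians(gantry_angle)
    cosφ, sinφ = math.cos(phi), math.sin(phi)

    pairs: dict[int, dict[str, list[tuple[float, float]]]] = {}
    for name, cs in ss.structures.items():
        for c in cs:
            k = mlc.pair_of_z(c.slice_z, iso[2])
            ivs = _project_poly(c.polygon(), cosφ, sinφ, (iso[0], iso[1]))
            pairs.setdefault(k, {}).setdefault(name, []).extend(ivs)
    for k in pairs:
        for name in pairs[k]:
            pairs[k][name] = _merge_intervals(pairs[k][name])
    return BEVProjection(gantry_angle, mlc, iso, pairs)


def measure_normalized_geometry(
    ss: StructureSet,
    gantry_angle: float,
    leaf_pair: int,
    target: str = PTV,
    oar: str = RECTUM,
    mlc: MLCSpec | None = None,
    iso: tuple[float, float, float] | None = None,
) -> NormalizedGeometry:
    """Measure (rho_oar, gamma) for one leaf pair in its CT layer(s).

    R_PTV and R_OAR are the projection half-widths of target and OAR on
    the BEV u-axis; the gap g is the edge-to-edge separation of the OAR
    and the target material in the layer (negative if they overlap).
    A leaf pair spanning several slices averages the per-slice values.
    """
    mlc = mlc or MLCSpec()
    iso = iso if iso is not None else ss.isocenter
    phi = math.radians(gantry_angle)
    cosφ, sinφ = math.cos(phi), math.sin(phi)
    z_lo, z_hi = mlc.pair_z_range(leaf_pair, iso[2])

    r_ptvs, r_oars, gaps = [], [], []
    for z in ss.slice_zs(target):
        if not (z_lo <= z < z_hi):
            continue
        tgt = ss.union_at(target, z)
        if tgt is None:
            continue
        t_ivs = _merge_intervals(_project_poly(tgt, cosφ, sinφ, (iso[0], iso[1])))
        r_ptvs.append((t_ivs[-1][1] - t_ivs[0][0]) / 2.0)
        og = ss.union_at(oar, z)
        if og is None or og.is_empty:
            continue
        o_ivs = _merge_intervals(_project_poly(og, cosφ, sinφ, (iso[0], iso[1])))
        r_oars.append((o_ivs[-1][1] - o_ivs[0][0]) / 2.0)
        if tgt.intersects(og):
            inter = tgt.intersection(og)
            depth = 0.0
            if not inter.is_empty and inter.area > _AREA_EPS:
                boundary = tgt.boundary
                parts = inter.geoms if hasattr(inter, "geoms") else [inter]
                for p in parts:
                    if hasattr(p, "exterior"):
                        for q in p.exterior.coords:
                            depth = max(depth, shapely.Point(q).distance(boundary))
            gaps.append(-depth)
        else:
            gaps.append(tgt.distance(og))

    if not r_ptvs:
        raise GeometryError(
            f"leaf pair {leaf_pair} does not intersect the {target} projection")
    r_ptv = float(np.mean(r_ptvs))
    if not r_oars:
        logger.debug("no %s projection for leaf pair %d: rho_oar = 0", oar, leaf_pair)
        return NormalizedGeometry(0.0, float("nan"), r_ptv, oar_present=False)
    r_oar = float(np.mean(r_oars))
    g = float(np.mean(gaps))
    return NormalizedGeometry(r_oar / r_ptv, g / r_ptv, r_ptv)


__all__ = [
    "BEVProjection", "BODY", "BOOST", "CTV", "Contour", "DeformationSpec",
    "GeometryError", "MLCSpec", "MarginSpec", "NormalizedGeometry", "PTV",
    "PhantomSpec", "ProstateSpec", "RECTUM", "StructureSet",
    "concentric_structure_set", "expand_margin",
    "generate_prostate_case", "generate_quasimodo", "large_deformation",
    "measure_normalized_geometry", "project_to_bev", "small_deformation",
]
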
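"""Structure generation, margins, BEV projection, normalized geometry."""

import math

import numpy as np
import pytest

from twostep_imrt import (Contour, DeformationSpec, GeometryError,
                          PhantomSpec, StructureSet, expand_margin,
                          generate_prostate_case, generate_quasimodo,
                          large_deformation, measure_normalized_geometry,
                          project_to_bev, small_deformation)
from twostep_imrt.geometry import (BODY, BOOST, PTV, RECTUM, _arc,
                                   concentric_structure_set)


def _circle(r, center=(0.0, 0.0), n=128):
    pts = _arc(r, 0.0, 2 * math.pi * (1 - 1 / n), n)
    return pts + np.asarray(center)


def _identical(ss1: StructureSet, ss2: StructureSet) -> bool:
    if ss1.names() != ss2.names():
        return False
    for name in ss1.names():
        c1, c2 = ss1.contours(name), ss2.contours(name)
        if len(c1) != len(c2):
            return False
        for a, b in zip(c1, c2):
            if a.slice_z != b.slice_z or not np.array_equal(a.points, b.points):
                return False
    return True


class TestQuasimodo:
    def test_zero_delta_is_identity(self):
        ct1, ct2 = generate_quasimodo(PhantomSpec(n_slices=4), 0.0)
        assert _identical(ct1, ct2)

    def test_oar_radius_change_at_constant_gap(self):
        ct1, ct2 = generate_quasimodo(PhantomSpec(n_slices=4), 0.05)
        for z in ct1.slice_zs(PTV):
            g1 = measure_normalized_geometry(ct1, 0.0, 0)
            g2 = measure_normalized_geometry(ct2, 0.0, 0)
            assert g1.rho_oar - g2.rho_oar == pytest.approx(0.05, abs=1e-6)
            assert g1.gamma == pytest.approx(g2.gamma, abs=2e-3)

    def test_target_gains_area_inwards(self):
        # shoelace-area oracle on the generated polygons
        ct1, ct2 = generate_quasimodo(PhantomSpec(n_slices=4), 0.05)
        for c1, c2 in zip(ct1.contours(PTV), ct2.contours(PTV)):
            x1, y1 = c1.points[:, 0], c1.points[:, 1]
            x2, y2 = c2.points[:, 0], c2.points[:, 1]
            a1 = 0.5 * abs(np.dot(x1, np.roll(y1, -1)) - np.dot(y1, np.roll(x1, -1)))
            a2 = 0.5 * abs(np.dot(x2, np.roll(y2, -1)) - np.dot(y2, np.roll(x2, -1)))
            assert a2 > a1

    @pytest.mark.parametrize("bad", [
        PhantomSpec(r_oar=60.0, gap=6.0, r_ptv=60.0),     # gap violates radius
        PhantomSpec(r_ptv=200.0),                          # target outside body
        PhantomSpec(opening_deg=0.0),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(GeometryError):
            generate_quasimodo(bad, 0.0)

    def test_delta_rho_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            generate_quasimodo(PhantomSpec(), 0.5)


class TestProstateCase:
    def test_zero_deformation_identity(self):
        ct1, ct2 = generate_prostate_case(3, DeformationSpec())
        assert _identical(ct1, ct2)

    def test_same_seed_bit_identical(self):
        a = generate_prostate_case(7, small_deformation())
        b = generate_prostate_case(7, small_deformation())
        assert _identical(a[0], b[0]) and _identical(a[1], b[1])

    def test_boost_shrink_regimes(self):
        ct1, ct2 = generate_prostate_case(1, large_deformation())
        assert ct2.volume(BOOST) / ct1.volume(BOOST) == pytest.approx(0.75, rel=0.02)
        s1, s2 = generate_prostate_case(2, small_deformation())
        assert s2.volume(BOOST) / s1.volume(BOOST) == pytest.approx(0.95, rel=0.02)

    def test_boost_never_overlaps_rectum(self):
        ct1, ct2 = generate_prostate_case(4, large_deformation())
        for ss in (ct1, ct2):
            for c in ss.contours(BOOST):
                rect = ss.union_at(RECTUM, c.slice_z)
                if rect is not None:
                    assert c.polygon().intersection(rect).area < 1e-6


class TestExpandMargin:
    def test_zero_margin_identity(self):
        base = [Contour(0.0, _circle(20.0))]
        out = expand_margin(base, [0.0], 2.5, 0.0)
        assert len(out) == 1
        assert out[0].polygon().symmetric_difference(
            base[0].polygon()).area < 1e-6

    def test_isotropic_circle_dilation(self):
        # polygon-dilation oracle: circle r=20 + 10 mm -> circle r=30
        base = [Contour(0.0, _circle(20.0))]
        out = expand_margin(base, [0.0], 2.5, 10.0)
        pts = out[0].points
        radii = np.hypot(pts[:, 0], pts[:, 1])
        assert radii.min() > 29.5 and radii.max() < 30.5

    def test_posterior_margin_limited(self):
        base = [Contour(0.0, _circle(20.0))]
        out = expand_margin(base, [0.0], 2.5, 10.0, posterior_mm=7.0)
        pts = out[0].points
        ymin = pts[:, 1].min()   # posterior = -y
        ymax = pts[:, 1].max()
        assert ymin == pytest.approx(-27.0, abs=0.5)
        assert ymax == pytest.approx(30.0, abs=0.5)

    def test_forbidden_region_excluded(self):
        base = [Contour(0.0, _circle(20.0))]
        forbidden = [Contour(0.0, _circle(15.0, center=(0.0, -30.0)))]
        out = expand_margin(base, [0.0], 2.5, 5.0, forbidden=forbidden)
        forb = forbidden[0].polygon()
        for c in out:
            assert c.polygon().intersection(forb).area < 1e-6

    def test_cross_slice_extension(self):
        zs = [0.0, 2.5, 5.0, 7.5, 10.0]
        base = [Contour(5.0, _circle(20.0))]
        out = expand_margin(base, zs, 2.5, 5.0)
        assert sorted({c.slice_z for c in out}) == [0.0, 2.5, 5.0, 7.5, 10.0]

    @pytest.mark.parametrize("m1,m2", [(2.0, 5.0), (0.0, 3.0), (5.0, 10.0)])
    def test_margin_monotonicity(self, m1, m2):
        base = [Contour(0.0, _circle(20.0))]
        a1 = sum(c.area for c in expand_margin(base, [0.0], 2.5, m1))
        a2 = sum(c.area for c in expand_margin(base, [0.0], 2.5, m2))
        assert a2 >= a1

    def test_negative_margin_rejected(self):
        with pytest.raises(GeometryError):
            expand_margin([Contour(0.0, _circle(5.0))], [0.0], 2.5, -1.0)


class TestBEVProjection:
    def _single(self, points, z=0.0):
        return StructureSet(
            {PTV: [Contour(z, points)],
             BODY: [Contour(z, _circle(200.0))]}, 2.5, 2.0)

    @pytest.mark.parametrize("angle", [0.0, 30.0, 90.0, 215.0])
    def test_centered_circle_interval(self, angle):
        ss = self._single(_circle(50.0))
        bev = project_to_bev(ss, angle)
        lo, hi = bev.hull(0, PTV)
        assert lo == pytest.approx(-50.0, abs=0.1)
        assert hi == pytest.approx(50.0, abs=0.1)

    @pytest.mark.parametrize("angle", [0.0, 45.0, 120.0, 300.0])
    def test_off_axis_circle_rotation_oracle(self, angle):
        # rotation-matrix oracle: center (c, d) projects to c*cos + d*sin
        c, d, r = 30.0, -12.0, 10.0
        ss = self._single(_circle(r, center=(c, d)))
        bev = project_to_bev(ss, angle)
        lo, hi = bev.hull(0, PTV)
        u_center = c * math.cos(math.radians(angle)) + d * math.sin(
            math.radians(angle))
        assert (lo + hi) / 2 == pytest.approx(u_center, abs=0.1)
        assert hi - lo == pytest.approx(2 * r, abs=0.2)

    def test_two_disjoint_structures_two_sorted_intervals(self):
        ss = StructureSet(
            {PTV: [Contour(0.0, _circle(10.0, center=(-40.0, 0.0))),
                   Contour(0.0, _circle(10.0, center=(40.0, 0.0)))],
             BODY: [Contour(0.0, _circle(200.0))]}, 2.5, 2.0)
        ivs = project_to_bev(ss, 0.0).intervals(0, PTV)
        assert len(ivs) == 2
        assert ivs[0][1] < ivs[1][0]
        assert ivs[0] == (pytest.approx(-50.0, abs=0.1), pytest.approx(-30.0, abs=0.1))


class TestNormalizedGeometry:
    @pytest.mark.parametrize("angle", [0.0, 40.0, 170.0, 265.0])
    def test_concentric_circles(self, angle):
        ss = concentric_structure_set(r_ptv=100.0, rho_oar=0.3, gamma=0.1)
        g = measure_normalized_geometry(ss, angle, 0)
        assert g.rho_oar == pytest.approx(0.3, abs=5e-3)
        assert g.gamma == pytest.approx(0.1, abs=5e-3)
        assert g.r_ptv == pytest.approx(100.0, abs=0.5)

    def test_scale_invariance(self):
        a = concentric_structure_set(r_ptv=60.0, rho_oar=0.25, gamma=0.15)
        b = concentric_structure_set(r_ptv=120.0, rho_oar=0.25, gamma=0.15)
        ga = measure_normalized_geometry(a, 10.0, 0)
        gb = measure_normalized_geometry(b, 10.0, 0)
        assert ga.rho_oar == pytest.approx(gb.rho_oar, abs=1e-3)
        assert ga.gamma == pytest.approx(gb.gamma, abs=1e-3)

    def test_absent_oar_flagged(self):
        ss = StructureSet(
            {PTV: [Contour(0.0, _circle(50.0))],
             RECTUM: [],
             BODY: [Contour(0.0, _circle(200.0))]}, 2.5, 2.0)
        g = measure_normalized_geometry(ss, 0.0, 0)
        assert g.rho_oar == 0.0
        assert not g.oar_present
        assert math.isnan(g.gamma)

    def test_pair_outside_target_rejected(self):
        ss = concentric_structure_set()
        with pytest.raises(GeometryError):
            measure_normalized_geometry(ss, 0.0, 50)
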
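"""S0/S1/S2 generation, the radial-model optimum, and the beta* table."""

import math

import numpy as np
import pytest

from twostep_imrt import (generate_s0, generate_s1, generate_s2,
                          optimize_beta_omega, project_to_bev)
from twostep_imrt.dose import blocked_rotation_dose, strip_rotation_dose
from twostep_imrt.geometry import (BODY, PTV, RECTUM, Contour, MLCSpec,
                                   NormalizedGeometry, StructureSet, _arc,
                                   concentric_structure_set)
from twostep_imrt.twostep import TwoStepError, measure_geometry_map
from oracles import grid_search_beta_omega


def _circle(r, center=(0.0, 0.0), n=180):
    return _arc(r, 0.0, 2 * math.pi * (1 - 1 / n), n) + np.asarray(center)


class TestOptimizeBetaOmega:
    def test_matches_grid_search_oracle(self):
        # exhaustive grid at 1e-3 resolution; agreement within one cell
        for rho_oar, gamma in [(0.3, 0.1), (0.2, 0.1), (0.4, 0.05),
                               (0.5, 0.0), (0.15, 0.2)]:
            f2g, om_g, b_g = grid_search_beta_omega(rho_oar, gamma)
            res = optimize_beta_omega(rho_oar, gamma, beta_bounds=(0.005, 0.3))
            # the continuous optimum can only improve on the grid, and the
            # grid point must sit within one cell of it
            assert res.f2_min <= f2g + 1e-9
            assert abs(res.f2_min - f2g) <= 1e-5
            assert abs(res.beta_opt - b_g) <= 1e-3
            # omega alone is weakly identifiable along the narrow-strip
            # ridge (omega*beta ~ const); the physically meaningful
            # product must agree
            assert res.omega_opt * res.beta_opt == pytest.approx(
                om_g * b_g, rel=0.02)

    def test_compensation_always_helps(self):
        for rho_oar in (0.1, 0.3, 0.5):
            for gamma in (0.0, 0.1, 0.2):
                res = optimize_beta_omega(rho_oar, gamma)
                assert res.f2_min < res.f2_no_s2

    def test_vanishing_oar_limit(self):
        res = optimize_beta_omega(0.02, 0.0)
        assert res.f2_min < 1e-4
        assert res.beta_opt < 0.03

    def test_fixed_omega_mode(self):
        res = optimize_beta_omega(0.3, 0.1, constraint=1.0)
        assert res.omega_opt == 1.0
        free = optimize_beta_omega(0.3, 0.1)
        assert free.f2_min <= res.f2_min + 1e-12

    @pytest.mark.parametrize("rho,gamma", [(0.0, 0.1), (1.0, 0.0), (0.5, 0.6)])
    def test_invalid_geometry_rejected(self, rho, gamma):
        with pytest.raises(TwoStepError):
            optimize_beta_omega(rho, gamma)

    def test_homogeneity_restoration(self):
        # S1 + omega_opt*S2 always narrows the target dose spread
        for rho_oar, gamma in [(0.1, 0.0), (0.3, 0.1), (0.5, 0.2)]:
            res = optimize_beta_omega(rho_oar, gamma)
            rho = np.linspace(rho_oar + gamma, 1.0, 2000)
            w = rho / np.trapezoid(rho, rho)
            s1 = blocked_rotation_dose(rho, rho_oar)
            both = s1 + res.omega_opt * strip_rotation_dose(rho, rho_oar,
                                                            res.beta_opt)

            def cv(d):
                mean = np.trapezoid(w * d, rho)
                var = np.trapezoid(w * (d - mean) ** 2, rho)
                return math.sqrt(var) / mean

            assert cv(both) < cv(s1)


class TestBetaStarTable:
    def test_monotone_in_rho(self, beta_table):
        for row in beta_table.beta_star:
            assert np.all(np.diff(row) > 0)
        for row in beta_table.beta_star_fixed:
            assert np.all(np.diff(row) > 0)

    def test_weak_gamma_dependence(self, beta_table):
        # regression bound on the measured gamma spread of beta*
        for values, bound in ((beta_table.beta_star, 0.20),
                              (beta_table.beta_star_fixed, 0.15)):
            ref = values.mean(axis=0)
            assert np.max(np.abs(values - ref) / ref) < bound

    def test_polynomial_consistent_at_nodes(self, beta_table):
        tol = beta_table.max_rel_residual + 1e-9
        for j, g in enumerate(beta_table.gamma_grid):
            for i, r in enumerate(beta_table.rho_grid):
                val = beta_table.lookup(g, r)
                assert abs(val - beta_table.beta_star[j, i]) <= (
                    tol * beta_table.beta_star[j, i])

    def test_zero_rho_gives_zero(self, beta_table):
        for g in beta_table.gamma_grid:
            assert beta_table.lookup(g, 0.0) == 0.0
            assert beta_table.lookup(g, 0.0, mode="fixed") == 0.0

    def test_out_of_domain_clamped_with_warning(self, beta_table):
        with pytest.warns(UserWarning):
            v = beta_table.lookup(0.0, 0.9)
        assert v == pytest.approx(beta_table.lookup(0.0, 0.6), rel=1e-9)

    def test_scale_free(self, beta_table):
        # the lookup consumes only dimensionless (gamma, rho); widths in mm
        # scale linearly with R_PTV by construction w = beta * R_PTV
        b = beta_table.lookup(0.1, 0.3)
        assert 0.0 < b < 1.0


class TestSegmentGeneration:
    def _bev(self, ss, angle=0.0):
        return project_to_bev(ss, angle)

    def test_s0_circle_chord_oracle(self):
        r = 40.0
        zs = [-6.0, -2.0, 2.0, 6.0]
        mlc = MLCSpec(leaf_width_mm=4.0)
        # spherical target: per-slice circle of chord radius
        structs = {PTV: [], BODY: []}
        for z in zs:
            chord = math.sqrt(max(r * r - z * z, 1.0))
            structs[PTV].append(Contour(z, _circle(chord)))
            structs[BODY].append(Contour(z, _circle(150.0)))
        ss = StructureSet(structs, 4.0, 2.0)
        seg = generate_s0(project_to_bev(ss, 0.0, mlc=mlc), PTV)
        for k, (lo, hi) in seg.leaves.items():
            z = (k + 0.5) * 4.0
            zc = min(zs, key=lambda zz: abs(zz - z))
            expected = math.sqrt(max(r * r - zc * zc, 1.0))
            assert lo == pytest.approx(-expected, abs=0.2)
            assert hi == pytest.approx(expected, abs=0.2)

    def test_s0_outside_extent_closed(self):
        ss = concentric_structure_set(n_slices=2)
        seg = generate_s0(self._bev(ss), PTV)
        assert set(seg.leaves) == {-1, 0}

    def test_s1_without_oar_equals_s0(self):
        ss = StructureSet(
            {PTV: [Contour(0.0, _circle(40.0))],
             RECTUM: [],
             BODY: [Contour(0.0, _circle(150.0))]}, 2.5, 2.0)
        bev = self._bev(ss)
        s0 = generate_s0(bev, PTV)
        s1 = generate_s1(bev, PTV, RECTUM)
        assert len(s1) == 1 and s1[0].side is None
        assert s1[0].leaves == s0.leaves

    def test_s1_interval_subtraction(self):
        ss = concentric_structure_set(r_ptv=80.0, rho_oar=0.3, gamma=0.1)
        s1 = generate_s1(self._bev(ss), PTV, RECTUM)
        assert {s.side for s in s1} == {"L", "R"}
        for s in s1:
            for lo, hi in s.leaves.values():
                if s.side == "L":
                    assert lo == pytest.approx(-80.0, abs=0.5)
                    assert hi == pytest.approx(-24.0, abs=0.5)
                else:
                    assert lo == pytest.approx(24.0, abs=0.5)
                    assert hi == pytest.approx(80.0, abs=0.5)

    def test_quasimodo_two_sided_s1_every_angle(self, quasimodo_pair):
        # interval-arithmetic oracle: the OAR shadow is interior at every
        # angle, so exactly two one-sided S1 segments per angle
        ct1, _ = quasimodo_pair
        for angle in (0.0, 50.0, 130.0, 220.0, 310.0):
            s1 = generate_s1(project_to_bev(ct1, angle), PTV, RECTUM)
            assert sorted(s.side for s in s1) == ["L", "R"]

    def test_s2_zero_rho_no_segments(self, beta_table):
        ss = StructureSet(
            {PTV: [Contour(0.0, _circle(40.0))],
             RECTUM: [],
             BODY: [Contour(0.0, _circle(150.0))]}, 2.5, 2.0)
        bev = self._bev(ss)
        ngeo = {0: NormalizedGeometry(0.0, float("nan"), 40.0, oar_present=False)}
        assert generate_s2(bev, ngeo, beta_table, PTV, RECTUM) == []

    def test_s2_width_matches_table_lookup(self, beta_table):
        ss = concentric_structure_set(r_ptv=80.0, rho_oar=0.3, gamma=0.1)
        bev = self._bev(ss)
        ngeo = measure_geometry_map(ss, 0.0, [-1, 0], PTV, RECTUM)
        segs = generate_s2(bev, ngeo, beta_table, PTV, RECTUM)
        assert {s.side for s in segs} == {"L", "R"}
        for s in segs:
            for k, (lo, hi) in s.leaves.items():
                g = ngeo[k]
                expected = beta_table.lookup(g.gamma, g.rho_oar) * g.r_ptv
                assert hi - lo == pytest.approx(expected, rel=1e-6)

    def test_s2_narrower_for_smaller_oar(self, beta_table):
        widths = {}
        for rho in (0.2, 0.3):
            ss = concentric_structure_set(r_ptv=80.0, rho_oar=rho, gamma=0.1)
            bev = self._bev(ss)
            ngeo = measure_geometry_map(ss, 0.0, [0], PTV, RECTUM)
            segs = generate_s2(bev, ngeo, beta_table, PTV, RECTUM)
            widths[rho] = sum(hi - lo for s in segs
                              for lo, hi in s.leaves.values())
        assert widths[0.2] < widths[0.3]

    def test_segments_within_target_hull(self, quasimodo_pair, beta_table):
        ct1, _ = quasimodo_pair
        bev = project_to_bev(ct1, 70.0)
        ngeo = measure_geometry_map(
            ct1, 70.0, [k for k in bev.pairs if bev.intervals(k, PTV)],
            PTV, RECTUM)
        for seg in [generate_s0(bev, PTV),
                    *generate_s1(bev, PTV, RECTUM),
                    *generate_s2(bev, ngeo, beta_table, PTV, RECTUM)]:
            for k, (lo, hi) in seg.leaves.items():
                t_lo, t_hi = bev.hull(k, PTV)
                assert hi >= lo
                assert lo >= t_lo - 1e-6 and hi <= t_hi + 1e-6

    def test_empty_target_projection_rejected(self):
        ss = StructureSet(
            {PTV: [],
             RECTUM: [Contour(0.0, _circle(10.0))],
             BODY: [Contour(0.0, _circle(150.0))]}, 2.5, 2.0)
        with pytest.raises(TwoStepError):
            generate_s0(project_to_bev(ss, 0.0), PTV)
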
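"""Isocenter relocation, MU transfer, S2 width adaptation, imitation."""

import numpy as np
import pytest

from twostep_imrt import DoseEngine, NormalizedGeometry
from twostep_imrt.adaptation import (AdaptationError, _map_pair, adapt_plan,
                                     adapt_s2_widths, imitate_finetuning,
                                     regenerate_with_mu_transfer,
                                     relocate_isocenter)
from twostep_imrt.dose import Plan, Segment
from twostep_imrt.finetune import LeafShiftRecord
from twostep_imrt.geometry import PTV


class TestRelocateIsocenter:
    def test_identical_geometry_zero_shift(self, quasimodo_pair):
        ct1, _ = quasimodo_pair
        assert relocate_isocenter(ct1, ct1) == (0.0, 0.0, 0.0)

    def test_translation_equivariance(self, quasimodo_pair):
        ct1, _ = quasimodo_pair
        t = (4.0, -6.0, 2.5)
        shift = relocate_isocenter(ct1, ct1.shifted(t))
        assert shift == pytest.approx(t, abs=1.0)

    def test_overlap_maximal_at_returned_shift(self, quasimodo_pair):
        # exhaustive-search oracle on probe shifts around the optimum
        ct1, ct2 = quasimodo_pair
        ct2 = ct2.shifted((2.0, 1.0, 0.0))
        shift = relocate_isocenter(ct1, ct2)

        def overlap(s):
            moved = ct1.shifted(s)
            total = 0.0
            for z in moved.slice_zs(PTV):
                a = moved.union_at(PTV, z)
                b = ct2.union_at(PTV, z)
                if a is not None and b is not None:
                    total += a.intersection(b).area
            return total

        best = overlap(shift)
        for dx in (-2.0, 0.0, 2.0):
            for dy in (-2.0, 0.0, 2.0):
                probe = (shift[0] + dx, shift[1] + dy, shift[2])
                assert overlap(probe) <= best + 1e-6

    def test_empty_target_rejected(self, quasimodo_pair):
        ct1, _ = quasimodo_pair
        with pytest.raises(AdaptationError):
            relocate_isocenter(ct1, ct1, targets=("Boost-nonexistent",))


class TestRegenerateWithMUTransfer:
    def test_identity_geometry_reproduces_plan(self, quasimodo_pair,
                                               quasimodo_native, beta_table):
        ct1, _ = quasimodo_pair
        plan2, _, _ = regenerate_with_mu_transfer(
            quasimodo_native, ct1, (0.0, 0.0, 0.0), beta_table)
        pre = {s.key: s for s in quasimodo_native.plan_pre.segments}
        assert {s.key for s in plan2.segments} == set(pre)
        for seg in plan2.segments:
            mate = pre[seg.key]
            assert seg.mu == mate.mu
            assert seg.leaves.keys() == mate.leaves.keys()
            for k in seg.leaves:
                assert seg.leaves[k] == pytest.approx(mate.leaves[k], abs=1e-9)

    def test_mu_ledger_audit(self, quasimodo_pair, quasimodo_native,
                             beta_table):
        # every CT2 segment's MU equals its CT1 key-mate's MU
        _, ct2 = quasimodo_pair
        plan2, _, _ = regenerate_with_mu_transfer(
            quasimodo_native, ct2, (0.0, 0.0, 0.0), beta_table)
        pre = {s.key: s.mu for s in quasimodo_native.plan_pre.segments}
        for seg in plan2.segments:
            assert seg.mu == pre[seg.key]
        assert plan2.total_mu == quasimodo_native.plan_pre.total_mu


def _s2_plan(widths: dict[int, float], side="R", anchor=10.0):
    leaves = {k: (anchor, anchor + w) for k, w in widths.items()}
    seg = Segment(0.0, leaves, mu=1.0, step_type="S2", target=PTV, side=side)
    return Plan([seg], {PTV: 60.0})


class TestAdaptS2Widths:
    def _geo(self, rho, gamma=0.1, pairs=(0, 1)):
        return {(0.0, PTV, k): NormalizedGeometry(rho, gamma, 60.0)
                for k in pairs}

    def test_identical_geometry_unchanged(self, beta_table):
        plan = _s2_plan({0: 5.0, 1: 7.0})
        out, ratios = adapt_s2_widths(plan, self._geo(0.3), self._geo(0.3),
                                      beta_table)
        for k, (lo, hi) in out.segments[0].leaves.items():
            assert hi - lo == pytest.approx(
                plan.segments[0].leaves[k][1] - plan.segments[0].leaves[k][0])
        assert all(r == pytest.approx(1.0) for r in ratios.popitem()[1].values())

    def test_smaller_oar_narrower_strips(self, beta_table):
        plan = _s2_plan({0: 5.0, 1: 7.0})
        out, _ = adapt_s2_widths(plan, self._geo(0.3), self._geo(0.2),
                                 beta_table)
        for k, (lo, hi) in out.segments[0].leaves.items():
            w0 = plan.segments[0].leaves[k][1] - plan.segments[0].leaves[k][0]
            assert hi - lo < w0

    def test_ratio_matches_table_lookup(self, beta_table):
        plan = _s2_plan({0: 5.0})
        out, _ = adapt_s2_widths(plan, self._geo(0.3), self._geo(0.22),
                                 beta_table)
        lo, hi = out.segments[0].leaves[0]
        expected = 5.0 * (beta_table.lookup(0.1, 0.22, mode="fixed")
                          / beta_table.lookup(0.1, 0.3, mode="fixed"))
        assert hi - lo == pytest.approx(expected, rel=1e-9)

    def test_anchoring_preserves_block_edge(self, beta_table):
        plan = _s2_plan({0: 5.0}, side="R", anchor=10.0)
        out, _ = adapt_s2_widths(plan, self._geo(0.3), self._geo(0.2),
                                 beta_table)
        assert out.segments[0].leaves[0][0] == pytest.approx(10.0)
        plan_l = _s2_plan({0: 5.0}, side="L", anchor=10.0)
        out_l, _ = adapt_s2_widths(plan_l, self._geo(0.3), self._geo(0.2),
                                   beta_table)
        assert out_l.segments[0].leaves[0][1] == pytest.approx(15.0)

    def test_mus_untouched(self, beta_table):
        plan = _s2_plan({0: 5.0})
        out, _ = adapt_s2_widths(plan, self._geo(0.3), self._geo(0.2),
                                 beta_table)
        assert out.total_mu == plan.total_mu


class TestImitateFinetuning:
    def test_zero_record_identity(self):
        plan = _s2_plan({0: 5.0, 1: 7.0})
        record = LeafShiftRecord(
            shifts={plan.segments[0].key: {}}, target_extents={PTV: (0, 1)})
        out = imitate_finetuning(plan, record, {PTV: (0, 1)})
        assert out.segments[0].leaves == plan.segments[0].leaves

    def test_identity_extent_mapping(self):
        plan = _s2_plan({0: 5.0, 1: 7.0})
        key = plan.segments[0].key
        record = LeafShiftRecord(
            shifts={key: {0: (-2.0, 2.0), 1: (0.0, -2.0)}},
            target_extents={PTV: (0, 1)})
        out = imitate_finetuning(plan, record, {PTV: (0, 1)})
        assert out.segments[0].leaves[0] == (8.0, 17.0)
        assert out.segments[0].leaves[1] == (10.0, 15.0)

    def test_extent_scaling_mapping_formula(self):
        # pair at fraction 0.4 of the CT1 extent maps to fraction 0.4 of
        # the CT2 extent
        ext1 = (0, 10)
        ext2 = (0, 15)
        assert _map_pair(6, ext1, ext2) == 4       # 6/15 = 0.4 -> 0.4*10
        assert _map_pair(0, ext1, ext2) == 0
        assert _map_pair(15, ext1, ext2) == 10

    def test_inverting_shift_closes_pair(self):
        plan = _s2_plan({0: 2.0})
        key = plan.segments[0].key
        record = LeafShiftRecord(shifts={key: {0: (4.0, -4.0)}},
                                 target_extents={PTV: (0, 0)})
        out = imitate_finetuning(plan, record, {PTV: (0, 0)})
        assert 0 not in out.segments[0].leaves


class TestAdaptPlan:
    def test_fixed_point_identical_dose(self, quasimodo_pair,
                                        quasimodo_native, beta_table):
        ct1, _ = quasimodo_pair
        res = adapt_plan(quasimodo_native, ct1, beta_table)
        assert res.shift == (0.0, 0.0, 0.0)
        eng = DoseEngine(ct1)
        d_nat = eng.compute(quasimodo_native.plan,
                            calibration=quasimodo_native.calibration)
        d_ad = eng.compute(res.adapted,
                           calibration=quasimodo_native.calibration)
        assert np.array_equal(d_nat.dose, d_ad.dose)

    def test_mu_conserved_through_every_step(self, quasimodo_adaptation,
                                             quasimodo_native):
        res = quasimodo_adaptation
        mu0 = quasimodo_native.plan.total_mu
        assert res.regenerated.total_mu == mu0
        assert res.width_adapted.total_mu == mu0
        assert res.adapted.total_mu == mu0
        assert res.mu_conserved()

    def test_mu_guard_warns_when_threshold_tightened(self, quasimodo_pair,
                                                     quasimodo_native,
                                                     beta_table):
        _, ct2 = quasimodo_pair
        with pytest.warns(UserWarning, match="MU-preserving"):
            res = adapt_plan(quasimodo_native, ct2, beta_table,
                             mu_guard=1e-4)
        assert res.mu_warning is not None
        assert res.mu_conserved()

    def test_missing_target_rejected(self, quasimodo_native, beta_table):
        ct2 = quasimodo_native.ss
        broken = type(ct2)(
            {k: v for k, v in ct2.structures.items() if k != PTV},
            ct2.slice_thickness, ct2.in_plane_resolution, ct2.isocenter)
        with pytest.raises(AdaptationError):
            adapt_plan(quasimodo_native, broken, beta_table)
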
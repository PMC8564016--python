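import math

import numpy as np
import pytest

import ffram as F
from ffram.errors import OccludedBranchError
from ffram.lesions import Lesion
from ffram.tree import TreeLocation
from ffram.units import MM, MMHG

from conftest import linear_taper_lesion


class TestAorticPressure:
    def test_cohort_mean_cuffs(self):
        # MAP(134/77) = 96 mmHg; hyperemic Pa = 89.2 mmHg
        assert math.isclose(F.mean_aortic_pressure(134, 77), 89.2, rel_tol=1e-12)

    def test_equal_pressures_rejected(self):
        with pytest.raises(ValueError):
            F.mean_aortic_pressure(100, 100)

    def test_zero_offset_gives_map(self):
        assert math.isclose(F.mean_aortic_pressure(134, 77, offset=0.0), 96.0,
                            rel_tol=1e-12)


class TestClosedForms:
    def test_poiseuille_hand_value(self, fluid):
        dp = F.poiseuille_drop(1e-6, fluid, 0.01, math.pi * 1.5e-3**2)
        assert math.isclose(dp, 17.605, rel_tol=1e-3)
        assert math.isclose(dp / MMHG, 0.132, rel_tol=5e-3)

    def test_poiseuille_zero_flow_and_linearity(self, fluid):
        assert F.poiseuille_drop(0.0, fluid, 0.01, 7e-6) == 0.0
        one = F.poiseuille_drop(1e-6, fluid, 0.01, 7e-6)
        two = F.poiseuille_drop(1e-6, fluid, 0.02, 7e-6)
        assert math.isclose(two, 2 * one, rel_tol=1e-14)

    def test_poiseuille_occluded(self, fluid):
        with pytest.raises(OccludedBranchError):
            F.poiseuille_drop(1e-6, fluid, 0.01, 0.0)

    def test_taper_limit_equals_poiseuille(self, fluid):
        dp_t = F.taper_viscous_drop(1e-6, fluid, 1e-3, 1e-3, 5e-3)
        dp_p = F.poiseuille_drop(1e-6, fluid, 5e-3, math.pi * 1e-6)
        assert math.isclose(dp_t, 44.563, rel_tol=1e-4)
        assert math.isclose(dp_t, dp_p, rel_tol=1e-12)

    def test_taper_hand_value(self, fluid):
        dp = F.taper_viscous_drop(1e-6, fluid, 1.5e-3, 1e-3, 5e-3)
        assert math.isclose(dp, 20.906, rel_tol=1e-3)

    def test_taper_bounded_by_end_radii(self, fluid):
        rng = np.random.default_rng(2)
        for _ in range(100):
            r1, r2 = sorted(rng.uniform(0.5e-3, 2.5e-3, 2), reverse=True)
            L, q = rng.uniform(2e-3, 10e-3), rng.uniform(5e-7, 5e-6)
            dp = F.taper_viscous_drop(q, fluid, r1, r2, L)
            lo = F.poiseuille_drop(q, fluid, L, math.pi * r1**2)
            hi = F.poiseuille_drop(q, fluid, L, math.pi * r2**2)
            assert lo - 1e-12 <= dp <= hi + 1e-12

    def test_contraction_hand_value(self, fluid):
        dp = F.contraction_loss(3e-6, fluid, 6e-6, 2e-6, 30.0)
        assert math.isclose(dp, 97.8, rel_tol=1e-3)

    def test_contraction_zero_cases(self, fluid):
        assert F.contraction_loss(3e-6, fluid, 6e-6, 2e-6, 0.0) == 0.0
        assert F.contraction_loss(3e-6, fluid, 6e-6, 6e-6, 30.0) == 0.0
        with pytest.raises(ValueError):
            F.contraction_loss(3e-6, fluid, 2e-6, 6e-6, 30.0)

    def test_expansion_hand_values(self, fluid):
        dp = F.expansion_loss(3e-6, fluid, 2e-6, 6e-6, 25.0)
        assert math.isclose(dp, 530.0, rel_tol=1e-9)  # zeta capped at 1
        dp10 = F.expansion_loss(3e-6, fluid, 2e-6, 6e-6, 10.0)
        assert math.isclose(dp10 / dp, 2.6 * math.sin(math.radians(10.0)),
                            rel_tol=1e-9)
        assert F.expansion_loss(3e-6, fluid, 6e-6, 6e-6, 25.0) == 0.0


def example_lesion():
    r_p = math.sqrt(6e-6 / math.pi)
    r_s = math.sqrt(2e-6 / math.pi)
    alpha = math.degrees(math.atan((r_p - r_s) / 3e-3))
    return Lesion(branch_id="x", s_prox=0.0, s_dist=10e-3,
                  s_throat_start=3e-3, s_throat_end=7e-3,
                  A_p=6e-6, A_s=2e-6, A_d=6e-6,
                  alpha=alpha, beta=alpha, ds=0.42)


class TestLesionDrop:
    def test_zero_flow_all_zero(self, fluid):
        bd = F.lesion_pressure_drop(example_lesion(), 0.0, fluid)
        assert bd.dp_ps == bd.dp_ss == bd.dp_sd == 0.0

    def test_uniform_lesion_reduces_to_poiseuille(self, fluid):
        les = Lesion(branch_id="x", s_prox=0.0, s_dist=10e-3,
                     s_throat_start=3e-3, s_throat_end=7e-3,
                     A_p=6e-6, A_s=6e-6, A_d=6e-6,
                     alpha=0.0, beta=0.0, ds=0.3)
        bd = F.lesion_pressure_drop(les, 3e-6, fluid)
        straight = F.poiseuille_drop(3e-6, fluid, 10e-3, 6e-6) / MMHG
        assert math.isclose(bd.dp1, straight, rel_tol=1e-12)

    def test_component_hand_values(self, fluid):
        bd = F.lesion_pressure_drop(example_lesion(), 3e-6, fluid)
        assert math.isclose(bd.dp_ss * MMHG, 263.9, rel_tol=2e-3)
        assert math.isclose(bd.dp1 * MMHG, 710.0, rel_tol=5e-3)
        assert math.isclose(bd.dp1, 5.33, rel_tol=1e-2)  # mmHg

    def test_oracle_equivalence(self, fluid):
        rng = np.random.default_rng(8)
        for _ in range(20):
            branch, lesion = linear_taper_lesion(rng)
            q = float(rng.uniform(1e-6, 6e-6))
            dp1 = F.lesion_pressure_drop(lesion, q, fluid).dp1
            oracle = F.oracle_pressure_drop(branch, [lesion], q, fluid,
                                            grid_step=0.02 * MM)
            assert abs(dp1 - oracle) / oracle <= 1e-4

    def test_sensitivity_directions(self, fluid):
        base = example_lesion()
        q0, dp0 = 3e-6, F.lesion_pressure_drop(example_lesion(), 3e-6, fluid).dp1
        # tighter throat
        les = example_lesion()
        les.A_s = 1.5e-6
        assert F.lesion_pressure_drop(les, q0, fluid).dp1 > dp0
        # more flow
        assert F.lesion_pressure_drop(base, 4e-6, fluid).dp1 > dp0
        # longer throat
        les2 = example_lesion()
        les2.s_dist, les2.s_throat_end = 14e-3, 11e-3
        assert F.lesion_pressure_drop(les2, q0, fluid).dp1 > dp0

    def test_dimensional_consistency(self, fluid):
        # SI computation converted with the pinned constant equals a
        # clinical-unit computation scaled symbolically
        q_ml_s, L_mm, A_mm2 = 3.0, 4.0, 2.0
        si = F.poiseuille_drop(q_ml_s * 1e-6, fluid, L_mm * 1e-3,
                               A_mm2 * 1e-6) / MMHG
        clinical = (8 * math.pi * fluid.mu * L_mm * q_ml_s / A_mm2**2) * (
            1e-3 * 1e-6 / (1e-6) ** 2) / MMHG
        assert math.isclose(si, clinical, rel_tol=1e-12)


class TestUpstreamAndProfile:
    def test_upstream_zero_length_path(self, fluid, patient):
        v = F.make_stenosed_vessel(F.StenosisSpec(ds_true=0.5, center_s=6.0,
                                                  L=10, L_ps=3, L_sd=3,
                                                  vessel_length=30))
        les = F.find_lesions(v.root)
        rest = F.allocate_branch_flows(v, 1.5)
        hyper = F.hyperemic_flows(v, rest, {"root": les})
        lcopy = les[0]
        lcopy.s_prox = 0.0  # lesion starting at the ostium
        assert F.upstream_drop(v, hyper, lcopy, fluid) == 0.0

    def test_upstream_matches_closed_form_on_uniform_branch(self, fluid):
        v = F.make_straight_tube(40, 1.5, 0.25)
        rest = F.allocate_branch_flows(v, 2.0)
        hyper = F.hyperemic_flows(v, rest, {})
        les = Lesion(branch_id="root", s_prox=30e-3, s_dist=38e-3,
                     s_throat_start=33e-3, s_throat_end=35e-3,
                     A_p=7e-6, A_s=3e-6, A_d=7e-6, alpha=10, beta=10, ds=0.35)
        dp2 = F.upstream_drop(v, hyper, les, fluid)
        closed = F.poiseuille_drop(8.0e-6, fluid, 30e-3,
                                   math.pi * 1.5e-3**2) / MMHG
        assert math.isclose(dp2, closed, rel_tol=1e-9)

    def test_two_branch_path_additive(self, fluid):
        t = F.make_bifurcating_tree(2, root_radius=1.5,
                                    child_ratios=(0.9, 0.9), step=0.25)
        rest = F.allocate_branch_flows(t, 2.0)
        hyper = F.hyperemic_flows(t, rest, {})
        child = t.branches["root.a"]
        les = Lesion(branch_id="root.a", s_prox=float(child.s[-1]) - 6e-3,
                     s_dist=float(child.s[-1]) - 1e-3,
                     s_throat_start=float(child.s[-1]) - 4e-3,
                     s_throat_end=float(child.s[-1]) - 3e-3,
                     A_p=5e-6, A_s=2e-6, A_d=5e-6, alpha=10, beta=10, ds=0.4)
        dp2 = F.upstream_drop(t, hyper, les, fluid)
        q_root = hyper.q_hyper["root"].q[0] * 1e-6
        q_child = hyper.q_hyper["root.a"].q[0] * 1e-6
        expect = (
            F.poiseuille_drop(q_root, fluid, t.root.length,
                              float(t.root.area[0]))
            + F.poiseuille_drop(q_child, fluid, les.s_prox,
                                float(child.area[0]))
        ) / MMHG
        assert math.isclose(dp2, expect, rel_tol=1e-9)

    def test_no_lesion_short_vessel_ffr_near_one(self, fluid, patient):
        v = F.make_straight_tube(5, 2.0, 0.5)
        rest = F.allocate_branch_flows(v, F.total_resting_flow(patient))
        hyper = F.hyperemic_flows(v, rest, {})
        prof = F.ffr_profile(v, hyper, [], 89.2, fluid)
        assert np.all(prof.ffr["root"] > 0.995)

    def test_ffr_arithmetic_and_interpolation(self, fluid):
        v = F.make_straight_tube(20, 1.5, 0.5)
        rest = F.allocate_branch_flows(v, 1.0)
        hyper = F.hyperemic_flows(v, rest, {})
        prof = F.ffr_profile(v, hyper, [], 90.0, fluid)
        # profile identity ffr = 1 - dp/pa
        np.testing.assert_allclose(
            prof.ffr["root"], 1 - prof.dp_cum["root"] / 90.0, rtol=1e-12)
        assert prof.at(TreeLocation("root", 0.0)) == 1.0
        i = 7
        s_i = prof.s["root"][i]
        assert prof.at(TreeLocation("root", float(s_i))) == prof.ffr["root"][i]
        mid = 0.5 * (prof.s["root"][3] + prof.s["root"][4])
        v_mid = prof.at(TreeLocation("root", float(mid)))
        lo, hi = sorted((prof.ffr["root"][4], prof.ffr["root"][3]))
        assert lo <= v_mid <= hi

    def test_q_zero_gives_ffr_one(self, fluid):
        v = F.make_stenosed_vessel(F.StenosisSpec(ds_true=0.5))
        les = F.find_lesions(v.root)
        from ffram.flow import BranchFlow, FlowAssignment
        zero = FlowAssignment(q_rest={"root": BranchFlow(
            breaks=np.array([]), q=np.array([0.0]))})
        prof = F.ffr_profile(v, zero, les, 90.0, fluid, hyperemic=False)
        np.testing.assert_array_equal(prof.ffr["root"], 1.0)

    def test_clamping_flags_profile(self, fluid, patient):
        v = F.make_stenosed_vessel(F.StenosisSpec(ds_true=0.9))
        res = F.analyze_tree(v, patient)
        assert res.profile.clamped
        assert np.all(res.profile.ffr["root"] >= 0.01)


class TestIschemia:
    @pytest.mark.parametrize("ffr,expected", [
        (0.80, True), (0.81, False), (0.72, True), (1.0, False),
    ])
    def test_threshold_inclusive(self, ffr, expected):
        assert F.classify_ischemic(ffr) is expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            F.classify_ischemic(0.0)
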
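"""Gait generation: yaw-control table, phase equations, schedules."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from antsim import config as cfg
from antsim.gait import (FKGaitParams, IKGaitParams, angle_series,
                         fk_leg_angles, gait_step, ik_leg_targets,
                         init_gait_state, make_gait_schedule, stride_to_body,
                         thc_joint_range)


class TestThcJointRange:
    @pytest.mark.parametrize("theta,left,right", [
        (0.0, -10.0, 10.0),     # mirrored forward stride
        (0.5, 0.0, 10.0),       # right-only stride -> left turn
        (-1.0, -10.0, -10.0),   # spin
        (1.0, 10.0, 10.0),      # spin the other way
        (-0.5, -10.0, 0.0),     # left-only stride -> right turn
    ])
    def test_turn_table(self, theta, left, right):
        assert thc_joint_range(theta, "left", 1, 10.0) == pytest.approx(left)
        assert thc_joint_range(theta, "right", 1, 10.0) == pytest.approx(right)

    def test_out_of_range_theta_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            r = thc_joint_range(2.5, "right", 1, 10.0)
        assert r == pytest.approx(thc_joint_range(1.0, "right", 1, 10.0))

    @given(st.floats(-1, 1), st.floats(0, 30))
    def test_mirror_symmetry(self, theta, sl):
        """Negating theta and swapping sides mirrors the stride ranges."""
        assert thc_joint_range(-theta, "left", 1, sl) == \
            pytest.approx(-thc_joint_range(theta, "right", 1, sl))
        assert thc_joint_range(-theta, "right", 1, sl) == \
            pytest.approx(-thc_joint_range(theta, "left", 1, sl))

    def test_continuity_through_zero(self):
        """An infinitesimal steering command must not reverse the stride."""
        for side in ("left", "right"):
            below = thc_joint_range(-1e-9, side, 1, 10.0)
            above = thc_joint_range(1e-9, side, 1, 10.0)
            assert abs(below - above) < 1e-6


class TestFKLegAngles:
    P = FKGaitParams(Sl=12.0, Sh=8.0, Sn=10)

    def test_swing1_start(self):
        R = 12.0
        a, b, g = fk_leg_angles("swing1", 0, R, self.P)
        assert (a, b, g) == (self.P.alpha0 - R, self.P.beta0, self.P.gamma0)

    def test_phase_boundaries_continuous(self):
        R, Sn = 12.0, self.P.Sn
        assert fk_leg_angles("swing1", Sn, R, self.P) == \
            pytest.approx(fk_leg_angles("swing2", 0, R, self.P))
        assert fk_leg_angles("swing2", Sn, R, self.P) == \
            pytest.approx(fk_leg_angles("stance", 0, R, self.P))
        assert fk_leg_angles("stance", 2 * Sn, R, self.P) == \
            pytest.approx(fk_leg_angles("swing1", 0, R, self.P))

    def test_out_of_range_step_raises(self):
        with pytest.raises(IndexError):
            fk_leg_angles("swing1", self.P.Sn + 1, 5.0, self.P)
        with pytest.raises(IndexError):
            fk_leg_angles("stance", -1, 5.0, self.P)

    def test_unknown_phase_raises(self):
        with pytest.raises(ValueError):
            fk_leg_angles("hover", 0, 5.0, self.P)


class TestIKLegTargets:
    P = IKGaitParams(L=0.1, H=0.05, theta=0.3, Sn=10)

    def test_swing_endpoints(self):
        rot, trans = ik_leg_targets("swing", 0, self.P)
        assert rot == pytest.approx((0, 0, self.P.theta))
        assert trans == pytest.approx((self.P.L / 2, 0, 0))
        rot, trans = ik_leg_targets("swing", self.P.Sn, self.P)
        assert rot == pytest.approx((0, 0, 0))
        assert np.allclose(trans, (-self.P.L / 2, 0, -self.P.H))

    def test_cycle_closure_stance_end_equals_swing_start(self):
        rot_a, trans_a = ik_leg_targets("stance", self.P.Sn, self.P)
        rot_b, trans_b = ik_leg_targets("swing", 0, self.P)
        assert np.allclose(rot_a, rot_b, atol=1e-12)
        assert np.allclose(trans_a, trans_b, atol=1e-12)

    def test_lift_profile_closes_in_z(self):
        p = IKGaitParams(L=0.1, H=0.05, Sn=10, swing_profile="lift")
        _, t0 = ik_leg_targets("swing", 0, p)
        _, t1 = ik_leg_targets("swing", p.Sn, p)
        assert t0[2] == pytest.approx(0.0, abs=1e-12)
        assert t1[2] == pytest.approx(0.0, abs=1e-12)

    def test_stride_frame_maps_stance_to_backward_sweep(self):
        _, t_start = ik_leg_targets("stance", 0, self.P)
        _, t_end = ik_leg_targets("stance", self.P.Sn, self.P)
        _, b_start = stride_to_body((0, 0, 0), t_start)
        _, b_end = stride_to_body((0, 0, 0), t_end)
        assert b_start[0] > b_end[0]       # front -> back in the body frame

    def test_out_of_range_step_raises(self):
        with pytest.raises(IndexError):
            ik_leg_targets("swing", 11, self.P)


class TestSchedules:
    @pytest.mark.parametrize("gait,n_swing", [
        ("tripod", 3), ("ripple", 2), ("wave", 1)])
    def test_airborne_count_constant(self, gait, n_swing):
        sched = make_gait_schedule(gait)
        Sn = 10
        cycle = sched.cycle_ticks(Sn, "FK")
        for t in range(cycle):
            count = sum(sched.in_swing(leg, t, Sn, "FK")
                        for leg in cfg.LEG_IDS)
            assert count == n_swing

    def test_tripod_partition(self):
        sched = make_gait_schedule("tripod")
        swinging = {leg for leg in cfg.LEG_IDS
                    if sched.in_swing(leg, 0, 10, "FK")}
        assert swinging == {"FR", "ML", "HL"}

    def test_unknown_gait_raises(self):
        with pytest.raises(ValueError):
            make_gait_schedule("gallop")


class TestGaitStep:
    def test_every_leg_visits_all_phases_in_one_cycle(self):
        params = FKGaitParams(Sn=5)
        state = init_gait_state("tripod", params)
        cycle = state.cycle_ticks()
        seen = {leg: set() for leg in cfg.LEG_IDS}
        from antsim.gait import _fk_phase_at
        for t in range(cycle):
            for leg in cfg.LEG_IDS:
                tau = state.schedule.local_tick(leg, t, params.Sn, "FK")
                seen[leg].add(_fk_phase_at(tau, params.Sn, cycle)[0])
        for leg in cfg.LEG_IDS:
            assert seen[leg] == {"swing1", "swing2", "stance"}

    @pytest.mark.parametrize("gait", ["tripod", "ripple", "wave"])
    def test_angle_series_continuity(self, gait, rng):
        """Per-tick jumps stay below max(|R|, Sh)/Sn across random params."""
        for _ in range(10):
            params = FKGaitParams(Sl=rng.uniform(2, 25),
                                  Sh=rng.uniform(2, 25),
                                  theta=rng.uniform(-1, 1),
                                  Sn=int(rng.integers(4, 15)))
            bound = max(params.Sl * 2, params.Sh) / params.Sn + 1e-9
            cycle = make_gait_schedule(gait).cycle_ticks(params.Sn, "FK")
            series = angle_series(gait, params, 2 * cycle)
            for leg in cfg.LEG_IDS:
                jumps = np.abs(np.diff(series[leg], axis=0))
                assert jumps.max() <= bound

    def test_mirror_property_of_angle_series(self):
        """Swapping sides and negating theta mirrors the generated series:
        hip-yaw angles negate, pitch angles are unchanged.  Mirror-partner
        legs sit half a tripod cycle apart in the schedule."""
        cycle, half = 24, 12                      # Sn=6 -> 4*Sn ticks
        for theta in (-0.8, -0.3, 0.0, 0.4, 1.0):
            s = angle_series("tripod", FKGaitParams(Sl=10, Sh=6,
                                                    theta=theta, Sn=6),
                             2 * cycle)
            sm = angle_series("tripod", FKGaitParams(Sl=10, Sh=6,
                                                     theta=-theta, Sn=6),
                              2 * cycle)
            for left, right in zip(cfg.LEFT_LEGS, cfg.RIGHT_LEGS):
                partner = np.roll(s[right], -half, axis=0)
                assert np.allclose(sm[left][:, 0], -partner[:, 0], atol=1e-9)
                assert np.allclose(sm[left][:, 1:], partner[:, 1:], atol=1e-9)

    def test_determinism(self, model):
        p = FKGaitParams()
        assert np.allclose(angle_series("ripple", p, 100)["FL"],
                           angle_series("ripple", p, 100)["FL"])

    def test_mode_params_mismatch_raises(self, model):
        state = init_gait_state("tripod", FKGaitParams(), "FK")
        with pytest.raises(TypeError):
            gait_step(state, IKGaitParams(), "FK")
        with pytest.raises(TypeError):
            init_gait_state("tripod", FKGaitParams(), "IK")

    def test_ik_mode_produces_straight_stance_sweep(self, model):
        """IK stance drags every tip straight backward in the body frame."""
        from antsim.body import leg_tip_body
        params = IKGaitParams(L=0.08, H=0.04, Sn=8)
        state = init_gait_state("tripod", params, "IK")
        cycle = state.cycle_ticks()
        tips = {leg: [] for leg in cfg.LEG_IDS}
        stance = {leg: [] for leg in cfg.LEG_IDS}
        for t in range(cycle):
            in_st = {leg: state.in_stance(leg) for leg in cfg.LEG_IDS}
            state, angles = gait_step(state, params, model=model)
            for leg in cfg.LEG_IDS:
                if in_st[leg]:
                    stance[leg].append(
                        leg_tip_body(model, leg, angles, check_limits=False))
        for leg in cfg.LEG_IDS:
            path = np.array(stance[leg])
            dx = np.diff(path[:, 0])
            dy = np.diff(path[:, 1])
            assert np.all(dx < 0)                       # monotone backward
            assert np.max(np.abs(dy)) < 1e-9            # no lateral drift
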
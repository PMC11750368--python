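"""Navigation controllers: CX path integration, steering, beacon shift,
Zernike compass, trail and plume rules."""
import copy
import math

import numpy as np
import pytest

from antsim.brain import (CompassMemory, CXState, PlumeTrackerState,
                          beacon_desired_shift, beacon_steering, cx_pi_step,
                          decode_home_vector, heading_encoding,
                          pi_closed_loop, plume_track_step, shift_from_delta,
                          sl_from_theta, steering_from_desired,
                          trail_follow_step, visual_compass_step,
                          zernike_moment)
from antsim.locomotion import wrap_angle


def _run_cx(headings, speeds, state=None):
    cx = state or CXState()
    for h, v in zip(headings, speeds):
        cx, theta, sl = cx_pi_step(cx, h, v)
    return cx


def _oracle_home_bearing(headings, speeds):
    """Brute-force displacement sum: the home vector is minus the sum of the
    per-tick velocity vectors."""
    vx = np.sum(speeds * np.cos(headings))
    vy = np.sum(speeds * np.sin(headings))
    return math.atan2(-vy, -vx)


class TestSpeedModulation:
    def test_clamp_bounds(self):
        thetas = np.linspace(-2, 2, 4001)
        sl = np.array([sl_from_theta(t) for t in thetas])
        assert sl.max() == pytest.approx(25.0)
        assert sl.min() == pytest.approx(5.0)

    def test_saturated_turn_gives_minimum_step(self):
        assert sl_from_theta(1.0) == pytest.approx(5.0)
        assert sl_from_theta(-1.7) == pytest.approx(5.0)
        assert sl_from_theta(0.0) == pytest.approx(25.0)


class TestCXPathIntegration:
    def test_stationary_agent_keeps_baseline_memory(self):
        cx = CXState()
        for _ in range(200):
            cx, theta, sl = cx_pi_step(cx, 1.0, 0.0)
        assert np.allclose(cx.cpu4, cx.baseline)
        assert abs(theta) < 1e-9
        assert sl == pytest.approx(25.0)

    def test_step_length_always_confined(self, rng):
        cx = CXState(noise=0.02, rng=rng)
        for _ in range(500):
            h = rng.uniform(-np.pi, np.pi)
            v = rng.uniform(0, 0.03)
            cx, theta, sl = cx_pi_step(cx, h, v)
            assert 5.0 <= sl <= 25.0

    def test_activities_stay_clamped(self, rng):
        cx = CXState()
        for _ in range(300):
            cx, *_ = cx_pi_step(cx, rng.uniform(-np.pi, np.pi),
                                rng.uniform(0, 0.05))
        for arr in (cx.tn2, cx.tb1, cx.cpu4, cx.cpu1):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_flat_memory_decodes_as_undefined(self):
        bearing, mag = decode_home_vector(CXState())
        assert math.isnan(bearing) and mag == 0.0

    def test_straight_east_outbound_points_home_west(self):
        cx = _run_cx(np.zeros(200), np.full(200, 0.01))
        bearing, mag = decode_home_vector(cx)
        assert abs(math.degrees(wrap_angle(bearing - math.pi))) < 15.0
        assert mag > 0.01

    def test_l_path_bearing_and_monotone_magnitude(self):
        h = np.concatenate([np.zeros(100), np.full(100, math.pi / 2)])
        v = np.full(200, 0.01)
        cx = _run_cx(h, v)
        bearing, mag = decode_home_vector(cx)
        assert abs(math.degrees(wrap_angle(bearing - math.radians(225)))) < 15
        _, mag_half = decode_home_vector(_run_cx(h[:100], v[:100]))
        assert mag > mag_half > 0

    def test_decode_matches_displacement_sum_oracle(self):
        """Twenty seeded outbound command routes, bearing error < 15 deg."""
        from antsim.scenarios import make_foraging_route
        for seed in range(20):
            r = make_foraging_route(200, 0.05, seed)
            cx = _run_cx(r["headings"], r["speeds"])
            bearing, mag = decode_home_vector(cx)
            oracle = _oracle_home_bearing(r["headings"], r["speeds"])
            assert abs(math.degrees(wrap_angle(bearing - oracle))) < 15.0

    def test_steering_turns_towards_home(self):
        # outbound due south; home is due north; facing east -> turn CCW
        cx = _run_cx(np.full(150, -math.pi / 2), np.full(150, 0.01))
        _, theta_east, _ = cx_pi_step(copy.deepcopy(cx), 0.0, 0.0)
        _, theta_west, _ = cx_pi_step(copy.deepcopy(cx), math.pi, 0.0)
        assert theta_east > 0 > theta_west

    def test_closed_loop_homing_returns_near_nest(self):
        from antsim.scenarios import make_foraging_route
        reached = 0
        for seed in range(8):
            r = make_foraging_route(200, 0.05, seed)
            cx = CXState(noise=0.01, rng=np.random.default_rng(seed + 1000))
            res = pi_closed_loop(r["headings"], r["speeds"],
                                 homing_ticks=2000, state=cx)
            if res["min_distance"] <= 0.1 * res["route_length"]:
                reached += 1
        assert reached >= 7

    def test_homing_recovers_most_of_the_outbound_distance(self):
        """Switching to homing shrinks the nest distance in every run, and
        on average recovers most of it (the agent may wander again after
        passing the nest, so the minimum is the right summary)."""
        from antsim.scenarios import make_foraging_route
        starts, recovered = [], []
        for seed in range(6):
            r = make_foraging_route(200, 0.05, seed)
            cx = CXState(noise=0.01, rng=np.random.default_rng(seed + 1))
            res = pi_closed_loop(r["headings"], r["speeds"],
                                 homing_ticks=1500, state=cx)
            d = res["distances"]
            assert d.min() < d[0]
            starts.append(d[0])
            recovered.append(d[0] - d.min())
        assert np.mean(recovered) > 0.5 * np.mean(starts)


class TestSteeringCircuit:
    def test_equal_encodings_give_zero(self):
        enc = heading_encoding(0.7)
        assert steering_from_desired(enc, enc) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("offset", [0.1, 0.5, math.pi / 2, 2.0])
    def test_sign_matches_shorter_turn_direction(self, offset):
        h = 0.3
        pos = steering_from_desired(heading_encoding(h),
                                    heading_encoding(h + offset))
        neg = steering_from_desired(heading_encoding(h),
                                    heading_encoding(h - offset))
        assert pos > 0 > neg

    def test_sign_correct_for_all_column_offsets(self):
        """Brute force over the 8 ring columns."""
        h = 0.0
        for k in range(1, 4):
            off = 2 * math.pi * k / 8
            assert steering_from_desired(heading_encoding(h),
                                         heading_encoding(h + off)) > 0
            assert steering_from_desired(heading_encoding(h),
                                         heading_encoding(h - off)) < 0

    def test_magnitude_small_at_aligned_and_opposed(self):
        offsets = np.linspace(-math.pi, math.pi, 73)
        mags = [abs(steering_from_desired(heading_encoding(0),
                                          heading_encoding(o)))
                for o in offsets]
        mid = max(mags)
        assert mags[36] < 1e-9                       # aligned
        assert mags[0] < 0.05 * mid and mags[-1] < 0.05 * mid   # opposed
        assert mid == pytest.approx(
            max(abs(steering_from_desired(heading_encoding(0),
                                          heading_encoding(o)))
                for o in offsets[18:55]))            # peak between the zeros


class TestBeaconShift:
    def test_centred_landmark_no_shift(self):
        assert shift_from_delta(0.0, 74) == (0, 0)

    def test_shift_examples(self):
        assert shift_from_delta(37.0, 74) == (3, 1)
        assert shift_from_delta(-50.0, 74) == (5, -1)

    def test_masks_to_shift(self):
        mask = np.zeros((19, 74), dtype=bool)
        mask[:, 0] = True                   # landmark at far left: Pl = 0
        shift, sign = beacon_desired_shift(mask, None, "left")
        assert sign == 1                    # delta = 37 -> turn left
        assert shift == 3

    def test_binocular_averages_both_eyes(self):
        left = np.zeros((19, 74), dtype=bool)
        right = np.zeros((19, 74), dtype=bool)
        left[:, 17], right[:, 57] = True, True      # deltas +20 and -20
        assert beacon_desired_shift(left, right, "binocular") == (0, 0)

    def test_empty_mask_signals_no_detection(self):
        empty = np.zeros((19, 74), dtype=bool)
        assert beacon_desired_shift(empty, None, "left") is None
        assert beacon_desired_shift(empty, empty, "binocular") is None

    def test_steering_sign_towards_landmark(self):
        left_turn = beacon_steering((2, 1), 0.4)
        right_turn = beacon_steering((2, -1), 0.4)
        assert left_turn > 0 > right_turn

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            beacon_desired_shift(None, None, "cyclopean")


class TestZernike:
    def test_uniform_image_zero_for_nonzero_repetition(self):
        z = zernike_moment(np.full((72, 72), 180.0), 7, 1)
        assert abs(z) < 1e-10

    def test_column_shift_rotates_phase_exactly(self, rng):
        img = rng.uniform(0, 255, (72, 72))
        z0 = zernike_moment(img, 7, 1)
        for cols in (1, 5, 19, 36):
            z = zernike_moment(np.roll(img, cols, axis=1), 7, 1)
            dphi = wrap_angle(np.angle(z) - np.angle(z0)
                              - 2 * math.pi * cols / 72)
            assert abs(math.degrees(dphi)) < 1e-9
            assert abs(z) == pytest.approx(abs(z0), rel=1e-12)

    def test_single_bright_pixel_phase_tracks_column(self):
        """A lone bright pixel's coefficient phase is set by its column."""
        def pixel_phase(c0):
            img = np.zeros((72, 72))
            img[20, c0] = 255.0
            return np.angle(zernike_moment(img, 7, 1))
        base = pixel_phase(0)
        for c0 in (10, 41, 63):
            got = wrap_angle(pixel_phase(c0) - base)
            want = wrap_angle(2 * math.pi * c0 / 72)
            assert abs(wrap_angle(got - want)) < 1e-9

    def test_invalid_parity_rejected(self):
        with pytest.raises(ValueError):
            zernike_moment(np.zeros((72, 72)), 7, 2)
        with pytest.raises(ValueError):
            zernike_moment(np.zeros((72, 72)), 1, 3)


class TestVisualCompass:
    def test_no_rotation_no_command(self, rng):
        img = rng.uniform(0, 255, (72, 72))
        mem = CompassMemory.from_image(img)
        theta, sl = visual_compass_step(img, mem)
        assert theta == 0.0 and sl == pytest.approx(0.0, abs=1e-12)

    def test_literal_command_mapping(self, rng):
        """theta = sign(delta), Sl = |delta/5| for the wrapped phase delta."""
        img = rng.uniform(0, 255, (72, 72))
        z_phase = np.angle(zernike_moment(img, 7, 1))
        for delta, want in [(2.5, (1.0, 0.5)), (-1.0, (-1.0, 0.2))]:
            mem = CompassMemory(phase0=wrap_angle(z_phase - delta),
                                magnitude0=1.0)
            theta, sl = visual_compass_step(img, mem)
            assert theta == want[0]
            assert sl == pytest.approx(want[1], abs=1e-9)

    def test_featureless_panorama_flagged(self):
        mem = CompassMemory(phase0=0.0)
        assert visual_compass_step(np.full((72, 72), 99.0), mem) is None

    def test_rotation_direction(self, rng):
        img = rng.uniform(0, 255, (72, 72))
        mem = CompassMemory.from_image(img)
        theta, sl = visual_compass_step(np.roll(img, 3, axis=1), mem)
        assert theta != 0 and sl > 0


class TestTrailRule:
    def test_on_trail_balanced_goes_straight(self, rng):
        assert trail_follow_step(950.0, 948.0, rng) == (0.0, 8.0)

    def test_edge_imbalance_steers_proportionally(self, rng):
        theta, sl = trail_follow_step(980.0, 120.0, rng)
        assert theta == pytest.approx(860.0 / 400.0)
        assert sl == 4.0

    def test_off_trail_random_search(self, rng):
        seen = set()
        for _ in range(20):
            theta, sl = trail_follow_step(50.0, 50.0, rng)
            assert sl == 3.0
            seen.add(theta)
        assert seen == {-1.0, 1.0}

    def test_one_sided_contact_counts_as_sensed(self, rng):
        theta, sl = trail_follow_step(0.0, 950.0, rng)
        assert sl == 4.0 and theta == pytest.approx(-950.0 / 400.0)


class TestPlumeTracker:
    def test_no_odour_searches_with_small_step(self):
        st = PlumeTrackerState(rng=np.random.default_rng(0))
        seen = set()
        for _ in range(20):
            st, theta, sl, directive = plume_track_step(
                st, 0.0, 0.0, (0.01, 0), (0.01, 0), 0.0)
            assert sl == 5.0 and directive == "sense"
            seen.add(theta)
        assert seen == {-1.0, 1.0}

    def test_detection_orients_upwind_then_surges(self):
        st = PlumeTrackerState(rng=np.random.default_rng(0))
        # wind blowing towards +x; upwind bearing is pi; heading pi-12deg
        h = math.pi - math.radians(12.0)
        st, theta, sl, directive = plume_track_step(
            st, 1.0, 0.5, (0.01, 0.0), (0.01, 0.0), h)
        assert theta == 1.0                     # turn CCW towards upwind
        assert sl == pytest.approx(7.0)         # min(5 + 12 mod 5, 15)
        assert directive == "surge"
        # two surge loops at Sl=15, theta=0, regardless of sensing
        st, theta, sl, directive = plume_track_step(st, 0, 0, (0, 0), (0, 0), h)
        assert (theta, sl) == (0.0, 15.0) and directive == "surge"
        st, theta, sl, directive = plume_track_step(st, 0, 0, (0, 0), (0, 0), h)
        assert (theta, sl) == (0.0, 15.0) and directive == "sense"
        # after the surge the tracker senses again (here: nothing -> search)
        st, theta, sl, directive = plume_track_step(st, 0, 0, (0, 0), (0, 0), h)
        assert sl == 5.0

    def test_aligned_upwind_keeps_small_step(self):
        st = PlumeTrackerState(rng=np.random.default_rng(0))
        st, theta, sl, _ = plume_track_step(
            st, 1.0, 0.5, (0.01, 0.0), (0.01, 0.0), math.pi)
        assert theta == 0.0 and sl == pytest.approx(5.0)

    def test_higher_concentration_side_selects_wind_sensor(self):
        st = PlumeTrackerState(rng=np.random.default_rng(0))
        # right antenna senses more; right wind points +y -> upwind -y
        st, theta, sl, _ = plume_track_step(
            st, 0.2, 1.0, (0.0, -0.01), (0.0, 0.01), -math.pi / 2)
        assert theta == 0.0                     # already facing upwind (-y)
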
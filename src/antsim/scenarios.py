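"""Scenario fixtures and the closed-loop scenario runner.

Each scenario wires the per-tick loop *sense -> controller -> (theta, Sl) ->
gait step -> leg FK -> stance odometry* for one of the navigation
behaviours: path integration, visual beacon approach, panoramic visual
compass, odour trail following and odour plume tracking (plus a plain
locomotion demo).  Sensory decisions are latched at gait-cycle boundaries
(one decision per gait loop), matching how the steering commands enter the
gait tables; the path-integration memory additionally integrates every tick.

All worlds are generated here from seeds; everything is reproducible
bit-for-bit given the scenario seed.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import config as cfg
from .body import KinematicModel, build_ant_model
from .brain import (CompassMemory, CXState, PlumeTrackerState,
                    beacon_desired_shift, beacon_steering, cx_pi_step,
                    sl_from_theta, trail_follow_step, plume_track_step,
                    visual_compass_step)
from .gait import FKGaitParams, init_gait_state
from .locomotion import BodyPose, TrajectoryLog, step_body, wrap_angle
from .plume import PlumeParams, plume_init, plume_step, concentration_at, wind_at
from .world import (AntennaState, Cylinder, Scene, Sphere, TrailMap,
                    antenna_sweep, antenna_tips_world, binarize_image,
                    render_binocular, render_panorama, trail_sensor_read)

__all__ = ["ScenarioConfig", "make_landmark_world", "make_trail_map",
           "make_foraging_route", "run_scenario", "SCENARIO_NAMES"]

SCENARIO_NAMES = ("path_integration", "visual_beacon", "visual_compass",
                  "trail_following", "plume_tracking", "locomotion_demo")


@dataclass
class ScenarioConfig:
    """Everything needed to run one scenario deterministically."""

    name: str
    seed: int
    ticks: int = 4000
    out_dir: str | None = None
    gait_type: str = "tripod"
    sl_deg: float = 15.0                    # cruise hip swing where fixed
    sn: int = cfg.DEFAULT_SN
    completion_radius: float | None = None  # default: one body length
    options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario: {self.name!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")


# ---------------------------------------------------------------------------
# Fixture generators
# ---------------------------------------------------------------------------

def make_landmark_world(spec: dict | None = None, seed: int = 0) -> Scene:
    """Landmark arena: one beacon cylinder plus optional distractors.

    ``spec`` keys (all optional): beacon_position (x, y), beacon_radius,
    beacon_height, n_distractors, distractor_region (radius), background.
    Overlapping primitives raise a validation error.
    """
    spec = dict(spec or {})
    rng = np.random.default_rng(seed)
    pos = tuple(spec.get("beacon_position", (0.0, 6.0)))
    radius = float(spec.get("beacon_radius", 0.6))
    height = float(spec.get("beacon_height", 3.0))
    prims = [Cylinder(center=pos, radius=radius, height=height, intensity=0.0)]
    n_extra = int(spec.get("n_distractors", 0))
    region = float(spec.get("distractor_region", 12.0))
    for _ in range(n_extra):
        c = (rng.uniform(-region, region), rng.uniform(-region, region))
        prims.append(Sphere(center=(c[0], c[1], 0.4),
                            radius=float(rng.uniform(0.2, 0.5)),
                            intensity=60.0))
    for i, a in enumerate(prims):
        for b in prims[i + 1:]:
            d = math.hypot(a.center[0] - b.center[0],
                           a.center[1] - b.center[1])
            if d < a.radius + b.radius:
                raise ValueError(
                    f"overlapping primitives at {a.center} and {b.center}")
    return Scene(primitives=prims,
                 background=float(spec.get("background", 255.0)))


def trail_centerline(curvature: float, length: float, seed: int,
                     start: tuple = (5.0, 0.0), heading: float = math.pi,
                     ds: float = 0.02) -> np.ndarray:
    """Seeded smooth centerline polyline, from ``start`` along ``heading``.

    ``curvature`` is the standard deviation of the smoothed heading drift in
    rad per unit arc length; 0 gives a straight line.
    """
    rng = np.random.default_rng(seed)
    n = max(int(round(length / ds)), 2)
    dh = rng.normal(0.0, 1.0, size=n)
    # smooth the white noise into a slowly-varying curvature profile
    kernel = np.ones(80) / 80.0
    dh = np.convolve(dh, kernel, mode="same")
    if dh.std() > 0:
        dh = dh / dh.std()
    headings = heading + np.cumsum(curvature * dh * ds)
    pts = np.zeros((n + 1, 2))
    pts[0] = start
    pts[1:, 0] = start[0] + np.cumsum(ds * np.cos(headings))
    pts[1:, 1] = start[1] + np.cumsum(ds * np.sin(headings))
    return pts


def make_trail_map(width: float, curvature: float = 0.1,
                   length: float = 7.0, seed: int = 0,
                   resolution: float = 40.0,
                   start: tuple = (5.0, 0.0),
                   heading: float = math.pi) -> TrailMap:
    """Rasterise a seeded smooth trail band of the requested width.

    The centerline depends only on (curvature, length, seed, start,
    heading); widening the trail keeps the centerline fixed.  Raises for
    degenerate geometry (non-positive width/length).
    """
    from PIL import Image, ImageDraw

    if width <= 0:
        raise ValueError("trail width must be positive")
    if length <= 0:
        raise ValueError("trail length must be positive")
    pts = trail_centerline(curvature, length, seed, start, heading)
    margin = width / 2 + 1.0
    x0, y0 = pts.min(axis=0) - margin
    x1, y1 = pts.max(axis=0) + margin
    W = int(math.ceil((x1 - x0) * resolution)) + 1
    H = int(math.ceil((y1 - y0) * resolution)) + 1
    img = Image.new("L", (W, H), 0)
    draw = ImageDraw.Draw(img)
    px = [(float((x - x0) * resolution), float((y - y0) * resolution))
          for x, y in pts]
    w_px = max(int(round(width * resolution)), 1)
    draw.line(px, fill=255, width=w_px, joint="curve")
    r = w_px / 2.0
    for p in (px[0], px[-1]):       # round caps at the ends
        draw.ellipse([p[0] - r, p[1] - r, p[0] + r, p[1] + r], fill=255)
    trail = TrailMap(raster=np.asarray(img, dtype=float),
                     origin=(x0, y0), resolution=resolution)
    trail.centerline = pts          # kept for goal placement / diagnostics
    return trail


def make_foraging_route(n_ticks: int, turn_noise: float = 0.03,
                        seed: int = 0, speed: float = 0.006) -> dict:
    """Correlated-random-walk command series for an outbound foraging trip.

    Starts at the origin with an initial heading uniform on [0, 2*pi); the
    per-tick heading executes a random walk with ``turn_noise`` std (rad).
    Returns headings, speeds and the integrated ideal positions.
    """
    if n_ticks < 1:
        raise ValueError("n_ticks must be >= 1")
    rng = np.random.default_rng(seed)
    h0 = rng.uniform(0.0, 2 * np.pi)
    steps = rng.normal(0.0, turn_noise, size=n_ticks) if turn_noise > 0 \
        else np.zeros(n_ticks)
    headings = h0 + np.cumsum(steps)
    speeds = np.full(n_ticks, speed)
    pos = np.zeros((n_ticks + 1, 2))
    pos[1:, 0] = np.cumsum(speeds * np.cos(headings))
    pos[1:, 1] = np.cumsum(speeds * np.sin(headings))
    return {"headings": headings, "speeds": speeds, "positions": pos,
            "start": (0.0, 0.0), "initial_heading": h0}


# ---------------------------------------------------------------------------
# Shared embodied-walk helper
# ---------------------------------------------------------------------------

class _Walker:
    """Embodied agent: gait + FK + odometry with per-cycle command latching."""

    def __init__(self, model: KinematicModel, gait_type: str, sn: int,
                 sl_deg: float, pose: BodyPose):
        self.model = model
        self.params = FKGaitParams(Sl=sl_deg, Sn=sn)
        self.state = init_gait_state(gait_type, self.params, "FK")
        self.cycle = self.state.cycle_ticks()
        self.pose = pose
        self.tips = None
        self.speed = 0.0            # per-tick displacement of the last step

    def at_cycle_boundary(self, tick: int) -> bool:
        return tick % self.cycle == 0

    def command(self, theta: float, sl_deg: float) -> None:
        sl_deg = float(np.clip(sl_deg, 0.0, 45.0))
        self.params = dataclasses.replace(self.params, theta=float(theta),
                                          Sl=sl_deg)

    def step(self) -> None:
        prev = self.pose
        self.state, self.pose, self.tips, _ = step_body(
            self.model, self.state, self.params, self.pose, self.tips)
        self.speed = math.hypot(self.pose.x - prev.x, self.pose.y - prev.y)


def _completion_radius(config: ScenarioConfig, model: KinematicModel) -> float:
    if config.completion_radius is not None:
        return float(config.completion_radius)
    return model.morphology.body["length"]


# ---------------------------------------------------------------------------
# Scenario implementations
# ---------------------------------------------------------------------------

def _run_path_integration(config: ScenarioConfig, model: KinematicModel):
    opts = config.options
    outbound_ticks = int(opts.get("outbound_ticks", 400))
    homing_ticks = int(opts.get("homing_ticks", 5 * outbound_ticks))
    turn_noise = float(opts.get("turn_noise", 0.05))
    route = make_foraging_route(max(outbound_ticks, 1), turn_noise,
                                config.seed)
    nest = np.zeros(2)

    walker = _Walker(model, config.gait_type, config.sn, config.sl_deg,
                     BodyPose(0.0, 0.0, route["initial_heading"]))
    cx = CXState(noise=float(opts.get("cx_noise", 0.01)),
                 rng=np.random.default_rng(config.seed + 2))
    traj = TrajectoryLog()
    theta_cmd, sl_cmd = 0.0, config.sl_deg
    path_len = 0.0

    for t in range(outbound_ticks):
        if walker.at_cycle_boundary(t):
            h_want = route["headings"][min(t, outbound_ticks - 1)]
            theta_cmd = float(np.clip(
                2.0 * wrap_angle(h_want - walker.pose.h) / math.pi, -1, 1))
            walker.command(theta_cmd, config.sl_deg)
        walker.step()
        path_len += walker.speed
        cx, _, _ = cx_pi_step(cx, walker.pose.h, walker.speed)
        traj.append(t, walker.pose, theta_cmd=theta_cmd, sl_cmd=config.sl_deg,
                    phase="outbound")

    turning_point = np.array([walker.pose.x, walker.pose.y])
    min_dist = float(np.linalg.norm(turning_point - nest))
    goal_radius = _completion_radius(config, model)
    time_to_goal = None
    for t in range(outbound_ticks, outbound_ticks + homing_ticks):
        cx, theta, sl = cx_pi_step(cx, walker.pose.h, walker.speed)
        if walker.at_cycle_boundary(t):
            theta_cmd, sl_cmd = theta, sl
            walker.command(theta_cmd, sl_cmd)
        walker.step()
        d = math.hypot(walker.pose.x, walker.pose.y)
        min_dist = min(min_dist, d)
        if time_to_goal is None and d <= goal_radius:
            time_to_goal = t - outbound_ticks
        traj.append(t, walker.pose, theta_cmd=theta_cmd, sl_cmd=sl_cmd,
                    phase="homing")

    final = math.hypot(walker.pose.x, walker.pose.y)
    metrics = {
        "route_length": path_len,
        "turning_point_distance": float(np.linalg.norm(turning_point)),
        "min_distance_to_nest": min_dist,
        "final_distance_to_nest": final,
        "completed": bool(min_dist <= goal_radius or path_len == 0.0),
        "time_to_goal": time_to_goal if path_len > 0 else 0,
        "homing_ratio": (min_dist / path_len) if path_len > 0 else 0.0,
    }
    return traj, metrics


def _sample_initial_heading(mode: str, rng: np.random.Generator) -> float:
    lo, hi = {"left": (0.0, math.pi / 2),
              "right": (math.pi / 2, math.pi),
              "binocular": (math.pi / 4, 3 * math.pi / 4)}[mode]
    return float(rng.uniform(lo, hi))


def _run_visual_beacon(config: ScenarioConfig, model: KinematicModel):
    opts = config.options
    mode = opts.get("mode", "binocular")
    scene = make_landmark_world(opts.get("world"), seed=config.seed)
    beacon = scene.primitives[0]
    rng = np.random.default_rng(config.seed)
    h0 = float(opts.get("initial_heading",
                        _sample_initial_heading(mode, rng)))
    walker = _Walker(model, config.gait_type, config.sn, config.sl_deg,
                     BodyPose(0.0, 0.0, h0))
    body = {k: v for k, v in model.morphology.body.items()}
    thr = cfg.CONTROLLER_DEFAULTS["binarize_threshold"]
    goal_radius = _completion_radius(config, model) + beacon.radius

    # initial command, held until the landmark is first detected: scan on
    # the spot rather than walk blind — monocular agents towards their
    # sighted visual field, binocular agents in a seeded random direction
    theta_cmd = {"left": 1.0, "right": -1.0,
                 "binocular": float(rng.choice([-1.0, 1.0]))}[mode]
    sl_cmd = sl_from_theta(theta_cmd)
    traj = TrajectoryLog()
    time_to_goal = None
    detected = 0

    for t in range(config.ticks):
        if walker.at_cycle_boundary(t):
            masks = {}
            for eye in ("left", "right"):
                if mode in (eye, "binocular"):
                    img = render_binocular(scene, walker.pose, eye, body)
                    masks[eye] = binarize_image(img, thr, scene.background)
            res = beacon_desired_shift(masks.get("left"), masks.get("right"),
                                       mode)
            if res is not None:
                detected += 1
                theta_cmd = beacon_steering(res, walker.pose.h)
                sl_cmd = sl_from_theta(theta_cmd)
            walker.command(theta_cmd, sl_cmd)
        walker.step()
        d = math.hypot(walker.pose.x - beacon.center[0],
                       walker.pose.y - beacon.center[1])
        traj.append(t, walker.pose, theta_cmd=theta_cmd, sl_cmd=sl_cmd,
                    dist_to_beacon=d)
        if d <= goal_radius:
            time_to_goal = t
            break

    df_ticks = [r for r in traj.records]
    # signed lateral offset from the start->beacon axis during the approach
    bx, by = beacon.center[0], beacon.center[1]
    axis = np.array([bx, by]) / math.hypot(bx, by)
    left_normal = np.array([-axis[1], axis[0]])     # +1 = left of the axis
    approach = [r for r in df_ticks
                if r["dist_to_beacon"] <= 0.5 * math.hypot(bx, by)]
    lateral = [float(np.dot([r["x"], r["y"]], left_normal))
               for r in approach]
    metrics = {
        "mode": mode,
        "initial_heading": h0,
        "completed": time_to_goal is not None,
        "time_to_goal": time_to_goal if time_to_goal is not None
        else config.ticks,
        "detections": detected,
        "mean_lateral_offset": float(np.mean(lateral)) if lateral else 0.0,
        "final_distance": df_ticks[-1]["dist_to_beacon"],
    }
    return traj, metrics


def _compass_scene() -> Scene:
    """Asymmetric landmark panorama with a strong order-7 signature."""
    prims = [
        Cylinder(center=(4.0, 0.0), radius=0.8, height=3.0, intensity=0.0),
        Cylinder(center=(-2.5, 3.5), radius=0.5, height=2.0, intensity=40.0),
        Sphere(center=(1.5, -4.0, 1.0), radius=1.0, intensity=20.0),
        Cylinder(center=(-3.0, -2.0), radius=0.3, height=1.5, intensity=80.0),
    ]
    return Scene(primitives=prims)


def _run_visual_compass(config: ScenarioConfig, model: KinematicModel):
    opts = config.options
    rotation_mode = opts.get("rotation_mode", "incremental")
    rate = float(opts.get("rotation_rate", math.radians(0.02)))  # rad/tick
    jump = float(opts.get("jump_angle", math.radians(25.0)))
    jump_every = int(opts.get("jump_every", 1200))
    scene = _compass_scene()
    walker = _Walker(model, config.gait_type, config.sn, 0.0,
                     BodyPose(0.0, 0.0, 0.0))
    pano0 = render_panorama(scene, walker.pose)
    memory = CompassMemory.from_image(pano0)
    h0 = walker.pose.h
    theta_cmd, sl_cmd = 0.0, 0.0
    traj = TrajectoryLog()

    for t in range(config.ticks):
        if rotation_mode == "incremental":
            scene.world_rotation = rate * t
        else:
            scene.world_rotation = jump * (t // jump_every)
        if walker.at_cycle_boundary(t):
            pano = render_panorama(scene, walker.pose)
            res = visual_compass_step(pano, memory)
            if res is not None:
                theta, sl_raw = res
                theta_cmd = theta
                sl_cmd = math.degrees(sl_raw)   # phase measure -> hip swing
            walker.command(theta_cmd, sl_cmd)
        walker.step()
        err = wrap_angle(walker.pose.h - scene.world_rotation - h0)
        traj.append(t, walker.pose, theta_cmd=theta_cmd, sl_cmd=sl_cmd,
                    world_rotation=scene.world_rotation, heading_error=err)

    errs = [abs(r["heading_error"]) for r in traj.records]
    settle = int(opts.get("settle_ticks", min(800, config.ticks // 4)))
    metrics = {
        "rotation_mode": rotation_mode,
        "max_error_after_settle": float(np.max(errs[settle:])) if
        len(errs) > settle else float(np.max(errs)),
        "final_error": errs[-1],
        "mean_abs_error": float(np.mean(errs)),
    }
    return traj, metrics


def _run_trail_following(config: ScenarioConfig, model: KinematicModel):
    opts = config.options
    width = float(opts.get("trail_width", 0.6))
    curvature = float(opts.get("curvature", 0.12))
    length = float(opts.get("length", 6.0))
    antenna_mode = opts.get("antenna_mode", "moving")
    trail = make_trail_map(width, curvature, length, config.seed)
    goal = trail.centerline[-1]
    goal_radius = _completion_radius(config, model)

    walker = _Walker(model, config.gait_type, config.sn,
                     cfg.CONTROLLER_DEFAULTS["trail_sl_on_deg"],
                     BodyPose(5.0, 0.0, math.pi))
    ant_state = AntennaState(mode=antenna_mode)
    rng = np.random.default_rng(config.seed + 1)
    traj = TrajectoryLog()
    theta_cmd, sl_cmd = 0.0, cfg.CONTROLLER_DEFAULTS["trail_sl_on_deg"]
    ol_cycle, or_cycle = 0.0, 0.0
    time_to_goal = None

    for t in range(config.ticks):
        angles = antenna_sweep(ant_state, t)
        tips = antenna_tips_world(model, walker.pose, angles)
        ol = trail_sensor_read(trail, tips["AL"])
        orr = trail_sensor_read(trail, tips["AR"])
        # the gait-loop decision uses the best reading each antenna saw
        # during the loop (the sweep widens the sampled band)
        ol_cycle = max(ol_cycle, ol)
        or_cycle = max(or_cycle, orr)
        if walker.at_cycle_boundary(t):
            theta_cmd, sl_cmd = trail_follow_step(ol_cycle, or_cycle, rng)
            theta_cmd = float(np.clip(theta_cmd, -1.0, 1.0))
            walker.command(theta_cmd, sl_cmd)
            ol_cycle, or_cycle = ol, orr
        walker.step()
        d = math.hypot(walker.pose.x - goal[0], walker.pose.y - goal[1])
        traj.append(t, walker.pose, theta_cmd=theta_cmd, sl_cmd=sl_cmd,
                    ol=ol, orr=orr, dist_to_goal=d)
        if d <= goal_radius:
            time_to_goal = t
            break

    metrics = {
        "antenna_mode": antenna_mode,
        "trail_width": width,
        "completed": time_to_goal is not None,
        "time_to_goal": time_to_goal if time_to_goal is not None
        else config.ticks,
        "final_distance_to_goal": traj.records[-1]["dist_to_goal"],
    }
    return traj, metrics


def _run_plume_tracking(config: ScenarioConfig, model: KinematicModel):
    opts = config.options
    params = opts.get("plume_params") or PlumeParams()
    preroll = int(opts.get("preroll_ticks", 600))
    rng = np.random.default_rng(config.seed)
    plume = plume_init(params, seed=config.seed)
    for _ in range(preroll):
        plume_step(plume)

    y0 = float(opts.get("start_y", rng.uniform(-0.3, 0.3)))
    start = (float(opts.get("start_x", 3.2)), y0)
    walker = _Walker(model, config.gait_type, config.sn,
                     cfg.CONTROLLER_DEFAULTS["plume_sl_search_deg"],
                     BodyPose(start[0], start[1], math.pi))
    tracker = PlumeTrackerState(rng=np.random.default_rng(config.seed + 1))
    ant_state = AntennaState(mode="fixed")
    source = np.array(params.source[:2])
    goal_radius = _completion_radius(config, model)
    traj = TrajectoryLog()
    theta_cmd, sl_cmd = 0.0, cfg.CONTROLLER_DEFAULTS["plume_sl_search_deg"]
    time_to_goal = None
    height = params.source[2]

    for t in range(config.ticks):
        plume_step(plume)
        if walker.at_cycle_boundary(t):
            tips = antenna_tips_world(model, walker.pose,
                                      antenna_sweep(ant_state, t))
            pl = np.array([tips["AL"][0], tips["AL"][1], height])
            pr = np.array([tips["AR"][0], tips["AR"][1], height])
            ol = concentration_at(plume, pl)
            orr = concentration_at(plume, pr)
            wl = wind_at(plume, pl)
            wr = wind_at(plume, pr)
            tracker, theta_cmd, sl_cmd, _ = plume_track_step(
                tracker, ol, orr, wl, wr, walker.pose.h)
            walker.command(theta_cmd, sl_cmd)
        walker.step()
        d = float(np.linalg.norm([walker.pose.x - source[0],
                                  walker.pose.y - source[1]]))
        traj.append(t, walker.pose, theta_cmd=theta_cmd, sl_cmd=sl_cmd,
                    dist_to_source=d, n_puffs=plume.live_count)
        if d <= goal_radius:
            time_to_goal = t
            break

    metrics = {
        "completed": time_to_goal is not None,
        "time_to_goal": time_to_goal if time_to_goal is not None
        else config.ticks,
        "final_distance_to_source": traj.records[-1]["dist_to_source"],
        "puff_bookkeeping_exact": plume.released - plume.culled
        == plume.live_count,
    }
    return traj, metrics


def _run_locomotion_demo(config: ScenarioConfig, model: KinematicModel):
    from .locomotion import run_locomotion
    n_cycles = int(config.options.get("n_cycles", 10))
    params = FKGaitParams(Sl=config.sl_deg, Sn=config.sn,
                          theta=float(config.options.get("theta", 0.0)))
    res = run_locomotion(model, config.gait_type, params, n_cycles)
    metrics = {"mean_speed": res["mean_speed"],
               "heading_change_per_cycle": res["heading_change_per_cycle"],
               "gait_type": config.gait_type}
    return res["trajectory"], metrics


_RUNNERS = {
    "path_integration": _run_path_integration,
    "visual_beacon": _run_visual_beacon,
    "visual_compass": _run_visual_compass,
    "trail_following": _run_trail_following,
    "plume_tracking": _run_plume_tracking,
    "locomotion_demo": _run_locomotion_demo,
}


def run_scenario(config: ScenarioConfig,
                 model: KinematicModel | None = None) -> dict:
    """Run a scenario; returns ``{"trajectory", "metrics"}`` and optionally
    writes ``trajectory.csv`` / ``metrics.json`` to ``config.out_dir``."""
    if model is None:
        model = build_ant_model()
    traj, metrics = _RUNNERS[config.name](config, model)
    metrics["scenario"] = config.name
    metrics["seed"] = config.seed
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traj.to_csv(out / f"{config.name}_trajectory.csv")
        with open(out / f"{config.name}_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, default=float)
    return {"trajectory": traj, "metrics": metrics}
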
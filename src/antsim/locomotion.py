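"""Kinematic locomotion: stance-foot odometry replacing a physics engine.

The body is advanced by assuming that every stance-phase leg tip is anchored
to the ground: the rigid planar motion (rotation + translation) that best
explains the stance tips' apparent motion in the body frame is found by a
least-squares fit and applied inversely to the body pose.  This preserves
the gait-dependent speed ordering and steering behaviour of the walking
model while staying deterministic and desk-scale.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config as cfg
from .body import KinematicModel, leg_tip_body
from .gait import GaitState, gait_step, init_gait_state

__all__ = ["BodyPose", "TrajectoryLog", "stance_odometry_update",
           "run_locomotion", "wrap_angle"]

log = logging.getLogger(__name__)


def wrap_angle(angle: float) -> float:
    """Wrap an angle (radians) to (-pi, pi]."""
    a = math.fmod(angle + math.pi, 2 * math.pi)
    if a <= 0:
        a += 2 * math.pi
    return a - math.pi


@dataclass(frozen=True)
class BodyPose:
    """Planar body pose: position (model units) and heading (radians, CCW
    from world +x, wrapped to (-pi, pi])."""

    x: float = 0.0
    y: float = 0.0
    h: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.x) and np.isfinite(self.y)
                and np.isfinite(self.h)):
            raise ValueError("pose coordinates must be finite")
        object.__setattr__(self, "h", wrap_angle(self.h))

    def body_to_world(self, p_body) -> np.ndarray:
        """Map a body-frame point (2- or 3-vector; z passes through)."""
        p = np.asarray(p_body, dtype=float)
        c, s = math.cos(self.h), math.sin(self.h)
        out = np.array([self.x + c * p[0] - s * p[1],
                        self.y + s * p[0] + c * p[1]])
        if p.shape[0] == 3:
            out = np.array([out[0], out[1], p[2]])
        return out


@dataclass
class TrajectoryLog:
    """Per-tick record of pose, motor commands and sensor readings."""

    records: list = field(default_factory=list)

    def append(self, tick: int, pose: BodyPose, **extras) -> None:
        if self.records and tick <= self.records[-1]["tick"]:
            raise ValueError("ticks must be strictly increasing")
        self.records.append({"tick": tick, "x": pose.x, "y": pose.y,
                             "h": pose.h, **extras})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Odometry
# ---------------------------------------------------------------------------

def stance_odometry_update(pose: BodyPose, tips_prev: dict, tips_next: dict
                           ) -> BodyPose:
    """Advance the body pose from the motion of ground-anchored stance tips.

    ``tips_prev``/``tips_next`` map stance-leg ids to tip xy positions in
    the body frame before and after the tick.  The rigid planar transform
    mapping the new tip positions back onto the old ones (least-squares
    rotation + translation) is the body's own motion expressed in its
    previous frame.  With no stance legs the pose is returned unchanged and
    a warning is logged.
    """
    legs = sorted(set(tips_prev) & set(tips_next))
    if not legs:
        log.warning("stance odometry update with zero stance legs; "
                    "pose unchanged")
        return pose
    A = np.array([tips_next[leg][:2] for leg in legs], dtype=float)
    B = np.array([tips_prev[leg][:2] for leg in legs], dtype=float)
    a_bar, b_bar = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - a_bar, B - b_bar
    sxx = float(np.sum(Ac * Bc))
    sxy = float(np.sum(Ac[:, 0] * Bc[:, 1] - Ac[:, 1] * Bc[:, 0]))
    if sxx == 0.0 and sxy == 0.0:
        phi = 0.0
    else:
        phi = math.atan2(sxy, sxx)
    c, s = math.cos(phi), math.sin(phi)
    R = np.array([[c, -s], [s, c]])
    t = b_bar - R @ a_bar
    # compose: world pose advances by (R, t) expressed in the old body frame
    ch, sh = math.cos(pose.h), math.sin(pose.h)
    dx = ch * t[0] - sh * t[1]
    dy = sh * t[0] + ch * t[1]
    return BodyPose(pose.x + dx, pose.y + dy, wrap_angle(pose.h + phi))


# ---------------------------------------------------------------------------
# Locomotion loop
# ---------------------------------------------------------------------------

def _all_tips_body(model: KinematicModel, angles) -> dict:
    return {leg: leg_tip_body(model, leg, angles, check_limits=False)
            for leg in cfg.LEG_IDS}


def step_body(model: KinematicModel, state: GaitState, params,
              pose: BodyPose, tips_prev: dict | None):
    """One tick of the walk loop: gait step, FK, odometry.

    Returns ``(new_state, new_pose, tips, angles)``.  ``tips_prev`` is the
    body-frame tip dict from the previous tick (None on the first tick).
    """
    stance_at_start = {leg: state.in_stance(leg) for leg in cfg.LEG_IDS}
    new_state, angles = gait_step(state, params, model=model)
    tips = _all_tips_body(model, angles)
    if tips_prev is not None:
        stance_legs = [leg for leg in cfg.LEG_IDS if stance_at_start[leg]]
        prev = {leg: tips_prev[leg] for leg in stance_legs}
        nxt = {leg: tips[leg] for leg in stance_legs}
        pose = stance_odometry_update(pose, prev, nxt)
    return new_state, pose, tips, angles


def run_locomotion(model: KinematicModel, gait_type: str, params,
                   n_cycles: int, theta_schedule=None, mode: str = "FK",
                   start_pose: BodyPose | None = None) -> dict:
    """Walk ``n_cycles`` gait cycles and log the emergent body motion.

    ``theta_schedule`` maps a cycle index to a rotation configuration
    (callable, sequence, or None for the params' constant theta).  Returns a
    dict with the :class:`TrajectoryLog`, mean speed (model units/tick) and
    net heading change per cycle (radians).
    """
    import dataclasses

    state = init_gait_state(gait_type, params, mode)
    cycle = state.cycle_ticks()
    pose = start_pose or BodyPose()
    traj = TrajectoryLog()
    tips_prev = None
    start_h = pose.h
    path_len = 0.0
    heading_unwrapped = pose.h

    n_ticks = n_cycles * cycle
    current = params
    for t in range(n_ticks):
        if theta_schedule is not None and t % cycle == 0:
            idx = t // cycle
            theta = (theta_schedule(idx) if callable(theta_schedule)
                     else theta_schedule[idx])
            current = dataclasses.replace(params, theta=float(theta))
        prev_pose = pose
        state, pose, tips_prev, _ = step_body(model, state, current, pose,
                                              tips_prev)
        path_len += math.hypot(pose.x - prev_pose.x, pose.y - prev_pose.y)
        heading_unwrapped += wrap_angle(pose.h - prev_pose.h)
        traj.append(t, pose, theta_cmd=current.theta,
                    sl_cmd=getattr(current, "Sl", getattr(current, "L", 0.0)))

    return {
        "trajectory": traj,
        "mean_speed": path_len / max(n_ticks, 1),
        "net_heading_change": heading_unwrapped - start_h,
        "heading_change_per_cycle": (heading_unwrapped - start_h)
        / max(n_cycles, 1),
        "cycle_ticks": cycle,
    }
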
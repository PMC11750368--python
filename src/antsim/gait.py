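"""Gait generation: per-leg joint-angle series for FK- and IK-based gaits.

A gait cycle is parameterised by the half-swing tick count ``Sn``.  In FK
mode a leg's swing is two half-phases (protract+lift, protract+lower) of
``Sn`` ticks each followed by a stance sweep; in IK mode the swing is a
single ``Sn``-tick tip trajectory.  Tripod, ripple and wave coordination
differ only in the per-leg phase offsets and the stance/swing duty ratio:
the stance sweep is stretched over the longer ground phase so that exactly
3, 2 or 1 legs are airborne at any tick.

The steering scalar ``theta`` (rotation configuration, clipped to [-1, 1])
asymmetrises the left/right hip-swing ranges via the yaw-control table:

    theta >= 0:  left R = Sl*d*(2*theta - 1),  right R = Sl*d
    theta <  0:  left R = -Sl*d,               right R = Sl*d*(2*theta + 1)

so theta=0 strides straight, theta=+1/-1 spins counter-/clockwise, and
intermediate values pivot around the slower side.  The two rows are exact
mirror images (negating theta and swapping sides mirrors the stride), which
keeps the walking direction continuous through theta=0.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import config as cfg
from .body import (JointAngles, KinematicModel, leg_inverse_kinematics,
                   rest_tip_position)

__all__ = [
    "FKGaitParams", "IKGaitParams", "GaitSchedule", "GaitState",
    "thc_joint_range", "fk_leg_angles", "ik_leg_targets",
    "make_gait_schedule", "gait_step", "stride_to_body",
]

GAIT_TYPES = ("tripod", "ripple", "wave")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FKGaitParams:
    """Forward-kinematics gait parameters (angles in degrees)."""

    Sl: float = cfg.DEFAULT_FK_GAIT["Sl"]       # hip swing
    Sh: float = cfg.DEFAULT_FK_GAIT["Sh"]       # lift swing
    d: int = cfg.DEFAULT_FK_GAIT["d"]           # +1 forwards, -1 backwards
    theta: float = cfg.DEFAULT_FK_GAIT["theta"]  # rotation configuration
    Sn: int = cfg.DEFAULT_FK_GAIT["Sn"]         # half-swing tick count
    alpha0: float = cfg.DEFAULT_FK_GAIT["alpha0"]
    beta0: float = cfg.DEFAULT_FK_GAIT["beta0"]
    gamma0: float = cfg.DEFAULT_FK_GAIT["gamma0"]

    def __post_init__(self):
        if self.Sl < 0 or self.Sh < 0:
            raise ValueError("Sl and Sh must be non-negative")
        if self.Sn < 1:
            raise ValueError("Sn must be >= 1")
        if self.d not in (-1, 1):
            raise ValueError("d must be -1 or +1")


@dataclass(frozen=True)
class IKGaitParams:
    """Inverse-kinematics gait parameters (stride lengths in model units)."""

    L: float = cfg.DEFAULT_IK_GAIT["L"]         # step length
    H: float = cfg.DEFAULT_IK_GAIT["H"]         # step height
    theta: float = cfg.DEFAULT_IK_GAIT["theta"]  # tip yaw, radians
    Sn: int = cfg.DEFAULT_IK_GAIT["Sn"]
    swing_profile: str = cfg.DEFAULT_IK_SWING_PROFILE   # "literal" | "lift"

    def __post_init__(self):
        if self.L < 0 or self.H < 0:
            raise ValueError("L and H must be non-negative")
        if self.Sn < 1:
            raise ValueError("Sn must be >= 1")
        if self.swing_profile not in ("literal", "lift"):
            raise ValueError("swing_profile must be 'literal' or 'lift'")


@dataclass(frozen=True)
class GaitSchedule:
    """Per-leg phase offsets (cycle fractions) and the swing duty fraction."""

    gait_type: str
    offsets: dict                   # leg -> fraction of cycle
    swing_fraction: float           # fraction of the cycle a leg is airborne

    def cycle_ticks(self, Sn: int, mode: str) -> int:
        swing_ticks = 2 * Sn if mode == "FK" else Sn
        return int(round(swing_ticks / self.swing_fraction))

    def local_tick(self, leg: str, tick: int, Sn: int, mode: str) -> int:
        cycle = self.cycle_ticks(Sn, mode)
        return (tick + int(round(self.offsets[leg] * cycle))) % cycle

    def in_swing(self, leg: str, tick: int, Sn: int, mode: str) -> bool:
        swing_ticks = 2 * Sn if mode == "FK" else Sn
        return self.local_tick(leg, tick, Sn, mode) < swing_ticks


def make_gait_schedule(gait_type: str) -> GaitSchedule:
    """Tripod (3 airborne), ripple (2) or wave (1, back-to-front) schedule."""
    if gait_type == "tripod":
        offsets = {"FR": 0.0, "ML": 0.0, "HL": 0.0,
                   "FL": 0.5, "MR": 0.5, "HR": 0.5}
        return GaitSchedule("tripod", offsets, 0.5)
    if gait_type == "ripple":
        offsets = {"FR": 0.0, "HL": 0.0,
                   "MR": 1 / 3, "FL": 1 / 3,
                   "HR": 2 / 3, "ML": 2 / 3}
        return GaitSchedule("ripple", offsets, 1 / 3)
    if gait_type == "wave":
        order = ("HR", "MR", "FR", "HL", "ML", "FL")
        offsets = {leg: i / 6 for i, leg in enumerate(order)}
        return GaitSchedule("wave", offsets, 1 / 6)
    raise ValueError(f"unknown gait type: {gait_type!r}")


# ---------------------------------------------------------------------------
# Yaw-control table and FK phase equations
# ---------------------------------------------------------------------------

def thc_joint_range(theta: float, side: str, d: int, Sl: float) -> float:
    """Signed hip-swing range R (degrees) of the thorax-coxa yaw joint.

    ``theta`` outside [-1, 1] is clipped with a warning: the steering
    circuits can emit unbounded values but the turn table is only defined on
    the unit interval.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if abs(theta) > 1.0:
        warnings.warn(
            f"rotation configuration {theta:.4g} outside [-1, 1]; clipped",
            RuntimeWarning, stacklevel=2)
        theta = float(np.clip(theta, -1.0, 1.0))
    if theta >= 0:
        return Sl * d * (2 * theta - 1) if side == "left" else Sl * d
    return -Sl * d if side == "left" else Sl * d * (2 * theta + 1)


def fk_leg_angles(phase: str, k: float, R: float, params: FKGaitParams
                  ) -> tuple:
    """(alpha, beta, gamma) in degrees for one leg at step ``k`` of a phase.

    Swing half 1 lifts while protracting from the rearmost hip angle; swing
    half 2 lowers while reaching the frontmost angle; stance sweeps the hip
    back with the tip on the ground.  ``k`` may be fractional (stretched
    stance in ripple/wave coordination).
    """
    Sn, Sh = params.Sn, params.Sh
    a0, b0, g0 = params.alpha0, params.beta0, params.gamma0
    if phase == "swing1":
        if not 0 <= k <= Sn:
            raise IndexError(f"swing1 step {k} outside [0, {Sn}]")
        return (-R + a0 + R * k / Sn, b0 + Sh * k / Sn, g0 + Sh * k / Sn)
    if phase == "swing2":
        if not 0 <= k <= Sn:
            raise IndexError(f"swing2 step {k} outside [0, {Sn}]")
        return (a0 + R * k / Sn, b0 + Sh - Sh * k / Sn, g0 + Sh - Sh * k / Sn)
    if phase == "stance":
        if not 0 <= k <= 2 * Sn:
            raise IndexError(f"stance step {k} outside [0, {2 * Sn}]")
        return (a0 + R - R * k / Sn, b0, g0)
    raise ValueError(f"unknown FK phase: {phase!r}")


# ---------------------------------------------------------------------------
# IK tip-target equations
# ---------------------------------------------------------------------------

def ik_leg_targets(phase: str, k: float, params: IKGaitParams) -> tuple:
    """Tip pose (rotation Euler triple, translation triple) at step ``k``.

    Poses are expressed in the stride frame of the gait equations, whose +x
    axis points towards the body's rear (see :func:`stride_to_body`); the
    swing z-profile follows the literal stride equations unless the ``lift``
    profile is selected.
    """
    L, H, th, Sn = params.L, params.H, params.theta, params.Sn
    if phase == "swing":
        if not 0 <= k <= Sn:
            raise IndexError(f"swing step {k} outside [0, {Sn}]")
        if params.swing_profile == "lift":
            z = -H * np.sin(np.pi * k / Sn)
        else:
            z = -H * k / Sn
        return ((0.0, 0.0, th - th * k / Sn), (L / 2 - L * k / Sn, 0.0, z))
    if phase == "stance":
        if not 0 <= k <= Sn:
            raise IndexError(f"stance step {k} outside [0, {Sn}]")
        return ((0.0, 0.0, th * k / Sn), (-L / 2 + L * k / Sn, 0.0, 0.0))
    raise ValueError(f"unknown IK phase: {phase!r}")


def stride_to_body(rotation: tuple, translation: tuple) -> tuple:
    """Map a stride-frame pose to the body frame.

    The stride frame is rotated half a turn about the y-axis relative to the
    walking direction (the gait equations were written for a robot facing
    the world's -x axis): x and z negate and the tip yaw flips sign, so the
    stance sweep runs front-to-back and a positive rotation configuration
    yaws the body counter-clockwise, matching the FK turn table.
    """
    yaw = -rotation[2]
    tx, ty, tz = translation
    return yaw, (-tx, ty, -tz)


# ---------------------------------------------------------------------------
# Gait state machine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitState:
    """Immutable per-tick gait state: schedule, tick counter and the
    parameter set latched at the current cycle boundary."""

    schedule: GaitSchedule
    mode: str                                   # "FK" | "IK"
    tick: int = 0
    active_params: object = None

    def cycle_ticks(self) -> int:
        return self.schedule.cycle_ticks(self.active_params.Sn, self.mode)

    def in_stance(self, leg: str) -> bool:
        return not self.schedule.in_swing(
            leg, self.tick, self.active_params.Sn, self.mode)


def _fk_phase_at(tau: int, Sn: int, cycle: int) -> tuple:
    if tau <= Sn:
        return "swing1", float(tau)
    if tau <= 2 * Sn:
        return "swing2", float(tau - Sn)
    return "stance", 2.0 * Sn * (tau - 2 * Sn) / (cycle - 2 * Sn)


def _ik_phase_at(tau: int, Sn: int, cycle: int) -> tuple:
    if tau <= Sn:
        return "swing", float(tau)
    return "stance", float(Sn) * (tau - Sn) / (cycle - Sn)


def init_gait_state(gait_type: str, params, mode: str = "FK") -> GaitState:
    _check_mode(params, mode)
    return GaitState(schedule=make_gait_schedule(gait_type), mode=mode,
                     tick=0, active_params=params)


def _check_mode(params, mode: str) -> None:
    if mode == "FK" and not isinstance(params, FKGaitParams):
        raise TypeError("FK mode requires FKGaitParams")
    if mode == "IK" and not isinstance(params, IKGaitParams):
        raise TypeError("IK mode requires IKGaitParams")
    if mode not in ("FK", "IK"):
        raise ValueError(f"unknown gait mode: {mode!r}")


def gait_step(state: GaitState, params, mode: str | None = None,
              model: KinematicModel | None = None) -> tuple:
    """Advance the gait one tick: returns ``(new_state, JointAngles)``.

    ``params`` is the *requested* parameter set; it is latched into the
    state only at a cycle boundary, so steering commands take effect between
    gait loops.  IK mode needs the kinematic ``model`` to convert tip
    targets into joint angles.
    """
    mode = mode or state.mode
    _check_mode(params, mode)
    if mode != state.mode:
        raise TypeError(f"state is in {state.mode} mode, got {mode}")

    active = state.active_params
    cycle = state.schedule.cycle_ticks(active.Sn, state.mode)
    if state.tick % cycle == 0:
        active = params
        cycle = state.schedule.cycle_ticks(active.Sn, state.mode)

    Sn = active.Sn
    triples = {}
    if mode == "FK":
        for leg in cfg.LEG_IDS:
            side = "left" if leg in cfg.LEFT_LEGS else "right"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                R = thc_joint_range(active.theta, side, active.d, active.Sl)
            tau = state.schedule.local_tick(leg, state.tick, Sn, "FK")
            phase, k = _fk_phase_at(tau, Sn, cycle)
            triples[leg] = fk_leg_angles(phase, k, R, active)
    else:
        if model is None:
            raise TypeError("IK mode requires a KinematicModel")
        for leg in cfg.LEG_IDS:
            tau = state.schedule.local_tick(leg, state.tick, Sn, "IK")
            phase, k = _ik_phase_at(tau, Sn, cycle)
            try:
                rot, trans = ik_leg_targets(phase, k, active)
                yaw_rad, off_body = stride_to_body(rot, trans)
                base = model.morphology.leg_bases[leg]
                off_leg = _rot_z_deg(-base["yaw_deg"]) @ np.asarray(off_body)
                target = rest_tip_position(model, leg) + off_leg
                triples[leg] = leg_inverse_kinematics(
                    model, leg, target, yaw_deg=np.degrees(yaw_rad))
            except Exception as exc:
                exc.add_note(f"while solving leg {leg}, phase {phase}, k={k}")
                raise

    angles = JointAngles.from_triples(triples)
    new_state = replace(state, tick=state.tick + 1, active_params=active)
    return new_state, angles


def _rot_z_deg(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def angle_series(gait_type: str, params, n_ticks: int, mode: str = "FK",
                 model: KinematicModel | None = None):
    """Convenience: generate ``n_ticks`` of joint angles as a dict of
    per-leg (n, 3) arrays."""
    state = init_gait_state(gait_type, params, mode)
    series = {leg: np.empty((n_ticks, 3)) for leg in cfg.LEG_IDS}
    for t in range(n_ticks):
        state, angles = gait_step(state, params, mode, model=model)
        for leg in cfg.LEG_IDS:
            series[leg][t] = angles.triple(leg)
    return series


def angle_series_frame(gait_type: str, params, n_ticks: int,
                       mode: str = "FK",
                       model: KinematicModel | None = None):
    """Tidy (tick, leg, joint, angle) table of a generated angle series,
    ready for CSV export."""
    import pandas as pd

    series = angle_series(gait_type, params, n_ticks, mode, model)
    rows = []
    for leg in cfg.LEG_IDS:
        for joint_idx, joint in enumerate(("ThCz", "CTr", "FTi")):
            for t in range(n_ticks):
                rows.append((t, leg, joint, series[leg][t, joint_idx]))
    return pd.DataFrame(rows, columns=["tick", "leg", "joint", "angle"])
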
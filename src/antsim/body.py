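"""Ant body model: morphology, joint tree, and single-leg forward/inverse
kinematics.

The body frame has +x forward, +y left, +z up.  Each leg hangs off the body
at a base position with a base yaw; within the leg-base frame the chain is

    ThCx (fixed, about x) -> ThCz (yaw alpha, about z) -> coxa
    -> CTr (pitch beta, about -y) -> femur
    -> FTi (pitch gamma, about -y) -> tibia
    -> TiTa (fixed, about -y) -> tarsus -> tip

Pitch joints rotate about the local -y axis so that a positive angle lifts
the tip (tip z increases), matching the gait equations where the lift swing
adds a positive increment to beta and gamma during protraction.

Angles at this layer are in degrees (the unit of the gait parameters);
:func:`homogeneous_transform` uses radians, as transforms conventionally do.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config as cfg

__all__ = [
    "AntMorphology",
    "KinematicModel",
    "JointAngles",
    "MorphologyError",
    "ReachabilityError",
    "JointLimitError",
    "build_ant_model",
    "homogeneous_transform",
    "leg_forward_kinematics",
    "leg_inverse_kinematics",
]


class MorphologyError(ValueError):
    """Raised when a morphology violates its structural invariants."""


class ReachabilityError(ValueError):
    """Raised when an inverse-kinematics target lies outside the leg's
    reachable annulus."""

    def __init__(self, leg: str, distance: float, lo: float, hi: float):
        self.leg, self.distance, self.lo, self.hi = leg, distance, lo, hi
        super().__init__(
            f"leg {leg}: planar target distance {distance:.6g} outside "
            f"reachable annulus [{lo:.6g}, {hi:.6g}]")


class JointLimitError(ValueError):
    """Raised when a commanded joint angle is outside its limit range."""

    def __init__(self, leg: str, joint: str, angle: float, lo: float, hi: float):
        self.leg, self.joint, self.angle = leg, joint, angle
        super().__init__(
            f"leg {leg}: joint {joint} angle {angle:.4g} deg outside "
            f"limits [{lo:.4g}, {hi:.4g}]")


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

@dataclass
class AntMorphology:
    """Scaled segment geometry of the ant body.

    All lengths/positions are stored already multiplied by ``scale``; the
    constructor receives natural-size values (see :mod:`antsim.config`).
    """

    scale: float = cfg.DEFAULT_SCALE
    leg_segments: dict = field(default_factory=dict)       # leg -> segment -> length
    leg_bases: dict = field(default_factory=dict)          # leg -> {pos, yaw_deg}
    antenna_segments: dict = field(default_factory=dict)   # {scape, funiculus}
    antenna_bases: dict = field(default_factory=dict)      # antenna -> {pos, yaw_deg}
    antenna_rest_deg: tuple = cfg.DEFAULT_ANTENNA_REST_DEG
    fixed_angles: dict = field(default_factory=lambda: dict(cfg.DEFAULT_FIXED_ANGLES))
    joint_limits: dict = field(default_factory=lambda: dict(cfg.DEFAULT_JOINT_LIMITS))
    body: dict = field(default_factory=dict)

    @classmethod
    def from_config(cls, conf: dict | None = None) -> "AntMorphology":
        conf = conf if conf is not None else cfg.default_config()
        s = float(conf["scale"])
        leg_segments = {
            leg: {seg: s * length
                  for seg, length in conf["leg_segments"][cfg.leg_group(leg)].items()}
            for leg in cfg.LEG_IDS
        }
        leg_bases = {
            leg: {"pos": tuple(s * v for v in conf["leg_bases"][leg]["pos"]),
                  "yaw_deg": float(conf["leg_bases"][leg]["yaw_deg"])}
            for leg in cfg.LEG_IDS
        }
        antenna_segments = {k: s * v for k, v in conf["antenna_segments"].items()}
        antenna_bases = {
            ant: {"pos": tuple(s * v for v in conf["antenna_bases"][ant]["pos"]),
                  "yaw_deg": float(conf["antenna_bases"][ant]["yaw_deg"])}
            for ant in cfg.ANTENNA_IDS
        }
        body = {k: s * v for k, v in conf["body"].items()}
        return cls(scale=s, leg_segments=leg_segments, leg_bases=leg_bases,
                   antenna_segments=antenna_segments, antenna_bases=antenna_bases,
                   antenna_rest_deg=tuple(conf["antenna_rest_deg"]),
                   fixed_angles=dict(conf["fixed_angles"]),
                   joint_limits={k: tuple(v) for k, v in conf["joint_limits"].items()},
                   body=body)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.scale <= 0:
            raise MorphologyError("scale must be strictly positive")
        for leg in cfg.LEG_IDS:
            if leg not in self.leg_segments or leg not in self.leg_bases:
                raise MorphologyError(f"missing leg definition: {leg}")
            for seg, length in self.leg_segments[leg].items():
                if not length > 0:
                    raise MorphologyError(
                        f"leg_segments[{leg}][{seg}] must be > 0, got {length}")
        for ant in cfg.ANTENNA_IDS:
            if ant not in self.antenna_bases:
                raise MorphologyError(f"missing antenna definition: {ant}")
        for seg, length in self.antenna_segments.items():
            if not length > 0:
                raise MorphologyError(
                    f"antenna_segments[{seg}] must be > 0, got {length}")
        # left/right mirror symmetry about the sagittal (xz) plane
        for left, right in zip(cfg.LEFT_LEGS, cfg.RIGHT_LEGS):
            if self.leg_segments[left] != self.leg_segments[right]:
                raise MorphologyError(
                    f"leg_segments asymmetric between {left} and {right}")
            pl, pr = self.leg_bases[left]["pos"], self.leg_bases[right]["pos"]
            if not (np.isclose(pl[0], pr[0]) and np.isclose(pl[1], -pr[1])
                    and np.isclose(pl[2], pr[2])):
                raise MorphologyError(
                    f"leg_bases positions asymmetric between {left} and {right}")
            if not np.isclose(self.leg_bases[left]["yaw_deg"],
                              -self.leg_bases[right]["yaw_deg"]):
                raise MorphologyError(
                    f"leg_bases yaw asymmetric between {left} and {right}")
        # hind legs longer than front legs (desert-ant morphology)
        front = sum(self.leg_segments["FL"].values())
        hind = sum(self.leg_segments["HL"].values())
        if not hind > front:
            raise MorphologyError(
                f"hind-leg total length ({hind}) must exceed front-leg "
                f"total length ({front})")

    def leg_total_length(self, leg: str) -> float:
        return float(sum(self.leg_segments[leg].values()))


# ---------------------------------------------------------------------------
# Kinematic model (joint tree)
# ---------------------------------------------------------------------------

#: Per-leg joint order; suffix letter = rotation axis (the paper's scheme).
LEG_JOINTS = ("ThCx", "ThCz", "CTr", "FTi", "TiTa")
ACTIVE_LEG_JOINTS = ("ThCz", "CTr", "FTi")
ANTENNA_JOINTS = ("ScPz", "ScPy", "PdFy")   # scape lateral/elevation, pedicel flexion
NECK_JOINTS = ("NkY", "NkZ")
ABDOMEN_JOINTS = ("AbY", "AbZ")


@dataclass(frozen=True)
class Joint:
    name: str                   # fully-qualified, e.g. "FL.ThCz"
    axis: tuple                 # unit rotation axis in the parent frame
    limits: tuple               # (lo, hi) degrees
    parent: str                 # parent segment name


@dataclass
class KinematicModel:
    """The full joint tree: 6 legs x 5 joints + 2 antennae x 3 + neck 2 +
    abdomen 2 = 40 joints, with 8 end-effector (tactile) points."""

    morphology: AntMorphology
    joints: dict = field(default_factory=dict)      # name -> Joint

    @property
    def joint_count(self) -> int:
        return len(self.joints)

    def leg_dof(self, leg: str) -> int:
        return sum(1 for name in self.joints if name.startswith(leg + "."))

    @property
    def end_effectors(self) -> tuple:
        return tuple(f"{leg}.tip" for leg in cfg.LEG_IDS) + \
            tuple(f"{ant}.tip" for ant in cfg.ANTENNA_IDS)

    def active_joint_names(self, leg: str) -> tuple:
        return tuple(f"{leg}.{j}" for j in ACTIVE_LEG_JOINTS)


@dataclass
class JointAngles:
    """Map from joint identifier to angle (degrees).

    ``triple(leg)`` returns the active (alpha, beta, gamma) of a leg; ThCx
    and TiTa are held at the morphology's fixed values.
    """

    angles: dict = field(default_factory=dict)

    def triple(self, leg: str) -> tuple:
        return (self.angles[f"{leg}.ThCz"], self.angles[f"{leg}.CTr"],
                self.angles[f"{leg}.FTi"])

    @classmethod
    def from_triples(cls, triples: dict, fixed_angles: dict | None = None
                     ) -> "JointAngles":
        fixed = fixed_angles or cfg.DEFAULT_FIXED_ANGLES
        angles = {}
        for leg, (a, b, g) in triples.items():
            angles[f"{leg}.ThCx"] = fixed["ThCx"]
            angles[f"{leg}.ThCz"] = a
            angles[f"{leg}.CTr"] = b
            angles[f"{leg}.FTi"] = g
            angles[f"{leg}.TiTa"] = fixed["TiTa"]
        if not all(np.isfinite(v) for v in angles.values()):
            raise ValueError("joint angles must be finite")
        return cls(angles)


def build_ant_model(morphology: AntMorphology | None = None) -> KinematicModel:
    """Construct the ant joint tree from a validated morphology.

    Raises :class:`MorphologyError` naming the offending field if the
    morphology violates an invariant.
    """
    if morphology is None:
        morphology = AntMorphology.from_config()
    morphology.validate()

    joints: dict[str, Joint] = {}
    wide = (-180.0, 180.0)
    for leg in cfg.LEG_IDS:
        axes = {"ThCx": (1, 0, 0), "ThCz": (0, 0, 1), "CTr": (0, -1, 0),
                "FTi": (0, -1, 0), "TiTa": (0, -1, 0)}
        parents = {"ThCx": "thorax", "ThCz": "thorax", "CTr": "coxa",
                   "FTi": "femur", "TiTa": "tibia"}
        for jname in LEG_JOINTS:
            limits = morphology.joint_limits.get(jname, wide)
            joints[f"{leg}.{jname}"] = Joint(
                name=f"{leg}.{jname}", axis=axes[jname],
                limits=tuple(limits), parent=parents[jname])
    for ant in cfg.ANTENNA_IDS:
        axes = {"ScPz": (0, 0, 1), "ScPy": (0, -1, 0), "PdFy": (0, -1, 0)}
        parents = {"ScPz": "head", "ScPy": "head", "PdFy": "scape"}
        for jname in ANTENNA_JOINTS:
            joints[f"{ant}.{jname}"] = Joint(
                name=f"{ant}.{jname}", axis=axes[jname], limits=wide,
                parent=parents[jname])
    for jname, axis in zip(NECK_JOINTS, ((0, -1, 0), (0, 0, 1))):
        joints[f"neck.{jname}"] = Joint(f"neck.{jname}", axis, wide, "thorax")
    for jname, axis in zip(ABDOMEN_JOINTS, ((0, -1, 0), (0, 0, 1))):
        joints[f"abdomen.{jname}"] = Joint(f"abdomen.{jname}", axis, wide, "thorax")
    return KinematicModel(morphology=morphology, joints=joints)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def homogeneous_transform(rotation, translation) -> np.ndarray:
    """4x4 rigid transform from an Euler triple (radians) and a translation.

    Euler order is roll-pitch-yaw about the fixed x, y, z axes, applied in
    that sequence (R = Rz @ Ry @ Rx), followed by the translation.
    """
    rx, ry, rz = (float(v) for v in rotation)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx
    T[:3, 3] = np.asarray(translation, dtype=float)
    return T


def _rot_z(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# Single-leg forward kinematics
# ---------------------------------------------------------------------------

def _planar_chain(morph: AntMorphology, leg: str, beta: float, gamma: float
                  ) -> tuple[float, float]:
    """Radial distance and height of the tip in the leg's vertical plane,
    measured from the leg base, for pitch angles in degrees."""
    seg = morph.leg_segments[leg]
    tita = morph.fixed_angles["TiTa"]
    b = np.radians(beta)
    bg = np.radians(beta + gamma)
    bgt = np.radians(beta + gamma + tita)
    r = (seg["coxa"] + seg["femur"] * np.cos(b) + seg["tibia"] * np.cos(bg)
         + seg["tarsus"] * np.cos(bgt))
    z = (seg["femur"] * np.sin(b) + seg["tibia"] * np.sin(bg)
         + seg["tarsus"] * np.sin(bgt))
    return float(r), float(z)


def leg_forward_kinematics(model: KinematicModel, leg: str,
                           angles: "JointAngles | tuple",
                           check_limits: bool = True) -> np.ndarray:
    """Tip position (3-vector) in the leg-base frame.

    ``angles`` may be a :class:`JointAngles` or a bare (alpha, beta, gamma)
    triple in degrees.  Raises :class:`JointLimitError` if a commanded angle
    is outside its joint's limits.
    """
    if leg not in cfg.LEG_IDS:
        raise ValueError(f"unknown leg id: {leg!r}")
    if isinstance(angles, JointAngles):
        alpha, beta, gamma = angles.triple(leg)
    else:
        alpha, beta, gamma = angles
    if check_limits:
        morph = model.morphology
        for jname, ang in zip(ACTIVE_LEG_JOINTS, (alpha, beta, gamma)):
            lo, hi = morph.joint_limits.get(jname, (-180.0, 180.0))
            if not (lo - 1e-9 <= ang <= hi + 1e-9):
                raise JointLimitError(leg, jname, ang, lo, hi)
    r, z = _planar_chain(model.morphology, leg, beta, gamma)
    a = np.radians(alpha)
    return np.array([r * np.cos(a), r * np.sin(a), z])


def leg_tip_body(model: KinematicModel, leg: str,
                 angles: "JointAngles | tuple", **kw) -> np.ndarray:
    """Tip position in the body frame (leg base pose applied)."""
    tip = leg_forward_kinematics(model, leg, angles, **kw)
    base = model.morphology.leg_bases[leg]
    return _rot_z(base["yaw_deg"]) @ tip + np.asarray(base["pos"])


def antenna_tip_body(model: KinematicModel, antenna: str, angles_deg
                     ) -> np.ndarray:
    """Antenna tip position in the body frame for (lateral, elevation,
    flexion) joint angles in degrees."""
    morph = model.morphology
    a1, a2, a3 = (np.radians(v) for v in angles_deg)
    scape = morph.antenna_segments["scape"]
    fun = morph.antenna_segments["funiculus"]
    # chain: Rz(a1) · Ry(-a2) · Tx(scape) · Ry(-a3) · Tx(funiculus)
    r = scape * np.cos(a2) + fun * np.cos(a2 + a3)
    z = scape * np.sin(a2) + fun * np.sin(a2 + a3)
    tip_local = np.array([r * np.cos(a1), r * np.sin(a1), z])
    base = morph.antenna_bases[antenna]
    return _rot_z(base["yaw_deg"]) @ tip_local + np.asarray(base["pos"])


# ---------------------------------------------------------------------------
# Single-leg inverse kinematics
# ---------------------------------------------------------------------------

def leg_inverse_kinematics(model: KinematicModel, leg: str, target,
                           yaw_deg: float = 0.0) -> tuple:
    """Solve (alpha, beta, gamma) in degrees for a tip target in the
    leg-base frame.

    ``yaw_deg`` is an additional yaw about the leg-base z-axis applied to the
    target before solving; it ends up absorbed into the ThCz angle.  The two
    pitch joints are solved in the leg's vertical plane by the law of
    cosines, taking the knee branch that matches the rest posture
    (gamma <= 0).  Raises :class:`ReachabilityError` for targets outside the
    reachable annulus.
    """
    if leg not in cfg.LEG_IDS:
        raise ValueError(f"unknown leg id: {leg!r}")
    morph = model.morphology
    seg = morph.leg_segments[leg]
    p = _rot_z(yaw_deg) @ np.asarray(target, dtype=float)
    alpha = np.degrees(np.arctan2(p[1], p[0]))

    # effective distal link: tibia + tarsus with the fixed TiTa bend
    tita = np.radians(morph.fixed_angles["TiTa"])
    ti, ta = seg["tibia"], seg["tarsus"]
    lt = float(np.hypot(ti + ta * np.cos(tita), ta * np.sin(tita)))
    rho = float(np.arctan2(ta * np.sin(tita), ti + ta * np.cos(tita)))

    pr = float(np.hypot(p[0], p[1])) - seg["coxa"]
    pz = float(p[2])
    f = seg["femur"]
    d = float(np.hypot(pr, pz))
    lo, hi = abs(f - lt), f + lt
    if not (lo - 1e-12 <= d <= hi + 1e-12):
        raise ReachabilityError(leg, d, lo, hi)
    d = min(max(d, lo), hi)

    cos_q2 = (d * d - f * f - lt * lt) / (2.0 * f * lt)
    cos_q2 = min(1.0, max(-1.0, cos_q2))
    q2 = -np.arccos(cos_q2)          # knee-down branch, consistent with rest
    phi = np.arctan2(pz, pr)
    beta = phi - np.arctan2(lt * np.sin(q2), f + lt * np.cos(q2))
    gamma = q2 - rho
    return (float(alpha), float(np.degrees(beta)), float(np.degrees(gamma)))


def rest_tip_position(model: KinematicModel, leg: str,
                      rest: dict | None = None) -> np.ndarray:
    """Tip position in the leg-base frame at the gait rest angles."""
    rest = rest or cfg.DEFAULT_GAIT_REST_DEG
    return leg_forward_kinematics(
        model, leg, (rest["alpha0"], rest["beta0"], rest["gamma0"]),
        check_limits=False)
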
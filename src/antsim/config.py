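"""Default model constants and scenario-configuration loading.

All morphology segment lengths, controller constants and gait defaults live
here as the single source of truth.  Lengths are given at the natural size of
a desert ant (metres) and multiplied by ``scale`` (default 100, i.e. a
centimetre-scale ant becomes a metre-scale model) when a morphology object is
built.  Angles used by the gait layer are in degrees; transform-level angles
are in radians (see :func:`antsim.body.homogeneous_transform`).
"""
from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

# ---------------------------------------------------------------------------
# Morphology defaults
# ---------------------------------------------------------------------------

LEG_IDS = ("FL", "ML", "HL", "FR", "MR", "HR")
LEFT_LEGS = ("FL", "ML", "HL")
RIGHT_LEGS = ("FR", "MR", "HR")
ANTENNA_IDS = ("AL", "AR")

#: Multiplier applied to every length below.
DEFAULT_SCALE = 100.0

#: Per-leg segment lengths (coxa, femur, tibia, tarsus) in metres at natural
#: ant size.  Hind legs are the longest, a hallmark of desert-ant morphology
#: (hind > middle > front total length).
DEFAULT_LEG_SEGMENTS = {
    "front": {"coxa": 0.0008, "femur": 0.0022, "tibia": 0.0018, "tarsus": 0.0014},
    "middle": {"coxa": 0.0008, "femur": 0.0025, "tibia": 0.0021, "tarsus": 0.0016},
    "hind": {"coxa": 0.0010, "femur": 0.0030, "tibia": 0.0026, "tarsus": 0.0019},
}

_LEG_GROUP = {"FL": "front", "FR": "front", "ML": "middle", "MR": "middle",
              "HL": "hind", "HR": "hind"}

#: Leg-base positions in the body frame (x forward, y left, z up), metres at
#: natural size, and base yaw (degrees, CCW from body +x) of the leg frame's
#: outward x-axis.  Left legs mirror right legs across the sagittal plane.
DEFAULT_LEG_BASES = {
    "FL": {"pos": (0.0030, 0.0012, 0.0), "yaw_deg": 60.0},
    "ML": {"pos": (0.0000, 0.0013, 0.0), "yaw_deg": 90.0},
    "HL": {"pos": (-0.0030, 0.0012, 0.0), "yaw_deg": 120.0},
    "FR": {"pos": (0.0030, -0.0012, 0.0), "yaw_deg": -60.0},
    "MR": {"pos": (0.0000, -0.0013, 0.0), "yaw_deg": -90.0},
    "HR": {"pos": (-0.0030, -0.0012, 0.0), "yaw_deg": -120.0},
}

#: Antenna segment lengths (scape, funiculus) and bases on the head.
DEFAULT_ANTENNA_SEGMENTS = {"scape": 0.0022, "funiculus": 0.0030}
DEFAULT_ANTENNA_BASES = {
    "AL": {"pos": (0.0048, 0.0005, 0.0015), "yaw_deg": 30.0},
    "AR": {"pos": (0.0048, -0.0005, 0.0015), "yaw_deg": -30.0},
}
#: Rest joint angles (degrees) of each antenna chain: (lateral z, base
#: elevation, mid flexion).  Elevation is negative so tips sit near the floor
#: where trail pheromone is sampled.
DEFAULT_ANTENNA_REST_DEG = (0.0, -25.0, -10.0)

#: Fixed (non-actuated in gait control) joint angles, degrees.
DEFAULT_FIXED_ANGLES = {"ThCx": 0.0, "TiTa": 0.0}

#: Joint limits, degrees, for the three actuated leg joints.
DEFAULT_JOINT_LIMITS = {
    "ThCz": (-90.0, 90.0),
    "CTr": (-90.0, 90.0),
    "FTi": (-150.0, 60.0),
}

#: Outward yaw of each eye's optical axis from the body axis (degrees).
#: Ant compound eyes face laterally; 0 gives parallel forward axes.
DEFAULT_EYE_TOE_OUT_DEG = 20.0

#: Body geometry used by sensor placement (metres at natural size).
DEFAULT_BODY = {
    "length": 0.010,        # nest/goal radii default to one body length
    "eye_height": 0.0030,
    "eye_forward": 0.0045,
    "eye_half_sep": 0.0012,
    "panorama_height": 0.0045,
}

# ---------------------------------------------------------------------------
# Gait defaults
# ---------------------------------------------------------------------------

#: Initial (rest) angles of the actuated joints, degrees.  The negative pitch
#: angles put the tips below the body on a virtual ground plane.
DEFAULT_GAIT_REST_DEG = {"alpha0": 0.0, "beta0": -30.0, "gamma0": -70.0}

#: Half-swing tick count; a full gait cycle of the tripod gait is 4*Sn ticks.
DEFAULT_SN = 10

DEFAULT_FK_GAIT = {"Sl": 15.0, "Sh": 15.0, "d": 1, "theta": 0.0,
                   "Sn": DEFAULT_SN, **DEFAULT_GAIT_REST_DEG}
#: IK gait stride defaults in model units (scale applied already: metres).
DEFAULT_IK_GAIT = {"L": 0.10, "H": 0.05, "theta": 0.0, "Sn": DEFAULT_SN}

#: Swing z-profile of the IK gait: "literal" descends to −H as printed in the
#: stride equations; "lift" raises the tip by H mid-swing and lands at 0.
DEFAULT_IK_SWING_PROFILE = "literal"

# ---------------------------------------------------------------------------
# Controller constants
# ---------------------------------------------------------------------------

CONTROLLER_DEFAULTS = {
    # -- path integration (central-complex model) --
    "k_pi": 3.0,            # motor scale on the CPU1 left-right difference
    "sl0_deg": 5.0,         # basis step length
    "slf_deg": 20.0,        # speed-modulation scale factor
    "cpu4_gain": 0.005,     # memory accumulation rate per tick
    "cpu4_decay": 0.0,
    "cpu4_baseline": 0.5,
    "v_max": 0.02,          # model units / tick used to normalise speed input
    # -- visual beacon --
    "k_vb": 0.15,
    "binarize_threshold": 18.0,   # midpoint of the empirical [10, 25] range
    "beacon_delta_mode": "center",  # "center" (Wvb/2 − Pl) or "width" (Wvb − Pl)
    # -- visual compass --
    "zernike_n": 7,
    "zernike_m": 1,
    "compass_divisor": 5.0,
    "compass_min_magnitude": 1e-9,
    # -- trail following --
    "trail_To": 900.0,
    "trail_Td": 5.0,
    "trail_kd": 400.0,
    "trail_sl_on_deg": 8.0,
    "trail_sl_edge_deg": 4.0,
    "trail_sl_search_deg": 3.0,
    # -- plume tracking --
    "plume_Top": 1e-6,
    "plume_sl_search_deg": 5.0,
    "plume_sl_surge_deg": 15.0,
    "plume_surge_loops": 2,
}

#: Trail sensor calibration: full-scale reading for a saturated (255) texel.
TRAIL_SENSOR_FULL_SCALE = 1000.0

#: Antenna sweep defaults (unspecified by the behavioural data; exposed here).
DEFAULT_ANTENNA_SWEEP = {"amplitude_deg": 30.0, "period_ticks": 40}

# ---------------------------------------------------------------------------
# Scenario-configuration loading
# ---------------------------------------------------------------------------


def default_config() -> dict[str, Any]:
    """A deep copy of every default block, ready for per-run overrides."""
    return copy.deepcopy({
        "scale": DEFAULT_SCALE,
        "leg_segments": DEFAULT_LEG_SEGMENTS,
        "leg_bases": DEFAULT_LEG_BASES,
        "antenna_segments": DEFAULT_ANTENNA_SEGMENTS,
        "antenna_bases": DEFAULT_ANTENNA_BASES,
        "antenna_rest_deg": DEFAULT_ANTENNA_REST_DEG,
        "fixed_angles": DEFAULT_FIXED_ANGLES,
        "joint_limits": DEFAULT_JOINT_LIMITS,
        "body": DEFAULT_BODY,
        "fk_gait": DEFAULT_FK_GAIT,
        "ik_gait": DEFAULT_IK_GAIT,
        "controller": CONTROLLER_DEFAULTS,
        "antenna_sweep": DEFAULT_ANTENNA_SWEEP,
    })


def _deep_update(base: dict, overrides: dict) -> dict:
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict[str, Any]:
    """Load a YAML/JSON scenario config merged over the package defaults."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _deep_update(cfg, loaded)
    if overrides:
        _deep_update(cfg, overrides)
    return cfg


def leg_group(leg: str) -> str:
    """Map a leg id (e.g. ``'ML'``) to its segment group (front/middle/hind)."""
    return _LEG_GROUP[leg]
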
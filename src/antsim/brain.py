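"""Insect-brain navigation controllers.

Five closed-loop controllers share the motor interface of the FK gait
(rotation configuration ``theta`` and hip swing ``Sl``):

* **Path integration** — a central-complex (CX) model: TN2 speed cells,
  an 8-column TB1 heading ring, 16 CPU4 memory cells that accumulate the
  outbound displacement (the home vector), and 16 CPU1 steering cells whose
  left/right activation difference sets ``theta``; the step length follows
  Sl = Sl0 + Slf*(1 - min(|theta|, 1)), confined to [5, 25] degrees.
* **Visual beacon** — copy-and-shift: the dark landmark's mean column in a
  binarised eye image offsets the current heading encoding by a shifted
  copy, and the same CPU1-style steering circuit turns towards it.
* **Visual compass** — the phase of the order-7 / repetition-1 Zernike
  moment of the 72x72 panorama, compared with the initially stored phase.
* **Odour trail following** — bilateral antennal comparison with empirical
  thresholds (on-trail To=900, left/right difference Td=5, scale kd=400).
* **Odour plume tracking** — cast/surge: random scanning below the odour
  threshold Top=1e-6; above it, orient towards the upwind direction on the
  higher-concentration side, then surge forward for two gait loops.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import config as cfg
from .locomotion import wrap_angle

__all__ = [
    "CXState", "CompassMemory", "PlumeTrackerState",
    "cx_pi_step", "decode_home_vector", "sl_from_theta",
    "beacon_desired_shift", "shift_from_delta", "beacon_steering",
    "heading_encoding", "steering_from_desired",
    "zernike_moment", "visual_compass_step", "trail_follow_step",
    "plume_track_step",
]

N_COLUMNS = 8
_PHI = 2 * np.pi * np.arange(N_COLUMNS) / N_COLUMNS


def _clip01(x):
    return np.clip(x, 0.0, 1.0)


def sl_from_theta(theta: float, sl0: float | None = None,
                  slf: float | None = None) -> float:
    """Speed-modulation rule: Sl = Sl0 + Slf*(1 - min(|theta|, 1)).

    With the default basis Sl0=5 deg and scale Slf=20 deg the step length is
    confined to [5, 25] degrees for any steering output."""
    c = cfg.CONTROLLER_DEFAULTS
    sl0 = c["sl0_deg"] if sl0 is None else sl0
    slf = c["slf_deg"] if slf is None else slf
    return sl0 + slf * (1.0 - min(abs(theta), 1.0))


# ---------------------------------------------------------------------------
# Central-complex path integration
# ---------------------------------------------------------------------------

@dataclass
class CXState:
    """Activations of the path-integration network (all clamped to [0, 1])."""

    tn2: np.ndarray = field(default_factory=lambda: np.zeros(2))
    tb1: np.ndarray = field(default_factory=lambda: np.zeros(N_COLUMNS))
    cpu4: np.ndarray = field(default_factory=lambda: np.full(
        2 * N_COLUMNS, cfg.CONTROLLER_DEFAULTS["cpu4_baseline"]))
    cpu1: np.ndarray = field(default_factory=lambda: np.zeros(2 * N_COLUMNS))
    gain: float = cfg.CONTROLLER_DEFAULTS["cpu4_gain"]
    decay: float = cfg.CONTROLLER_DEFAULTS["cpu4_decay"]
    baseline: float = cfg.CONTROLLER_DEFAULTS["cpu4_baseline"]
    k_pi: float = cfg.CONTROLLER_DEFAULTS["k_pi"]
    v_max: float = cfg.CONTROLLER_DEFAULTS["v_max"]
    noise: float = 0.0              # steering-cell noise std (0 = exact)
    rng: np.random.Generator | None = None

    def validate(self) -> None:
        assert self.tn2.shape == (2,) and self.tb1.shape == (N_COLUMNS,)
        assert self.cpu4.shape == (2 * N_COLUMNS,)
        assert self.cpu1.shape == (2 * N_COLUMNS,)


def heading_encoding(h: float) -> np.ndarray:
    """8-column sinusoidal heading-ring (TB1-style) encoding of ``h``."""
    return 0.5 * (1.0 + np.cos(h - _PHI))


def cx_pi_step(state: CXState, heading: float, speed: float) -> tuple:
    """One tick of the CX path-integration network.

    ``speed`` is the body speed in model units/tick (>= 0), projected by the
    TN2 cells onto two axes at +-45 degrees from the body axis; TB1 encodes
    the heading sinusoidally with cross-inhibition (the anti-phase half of
    the ring is suppressed); CPU4 integrates TN2 gated by (1 - TB1) so the
    memory bump points home; CPU1 compares the memory shifted by one column
    against the current heading ring.  Returns ``(state, theta, Sl_deg)``.
    """
    v = max(float(speed), 0.0) / state.v_max
    state.tn2 = _clip01(np.array([v, v]) * math.cos(math.pi / 4))
    state.tb1 = _clip01(heading_encoding(heading))

    for half, tn2 in ((0, state.tn2[0]), (1, state.tn2[1])):
        sl = slice(half * N_COLUMNS, (half + 1) * N_COLUMNS)
        # signed displacement integration: the (1 - TB1) gate measured about
        # the ring midpoint, so memory accumulates against the travel
        # direction on the way out and depletes on the way home
        update = state.gain * tn2 * ((1.0 - state.tb1) - 0.5) \
            - state.decay * (state.cpu4[sl] - state.baseline)
        state.cpu4[sl] = _clip01(state.cpu4[sl] + update)

    left = _clip01(np.roll(state.cpu4[:N_COLUMNS], 1) - state.tb1)
    right = _clip01(np.roll(state.cpu4[N_COLUMNS:], -1) - state.tb1)
    state.cpu1 = np.concatenate([left, right])
    if state.noise > 0:
        if state.rng is None:
            state.rng = np.random.default_rng(0)
        state.cpu1 = _clip01(state.cpu1
                             + state.rng.normal(0, state.noise, 2 * N_COLUMNS))
        left, right = state.cpu1[:N_COLUMNS], state.cpu1[N_COLUMNS:]
    theta = state.k_pi * float(left.sum() - right.sum())
    return state, theta, sl_from_theta(theta)


def decode_home_vector(state: CXState, eps: float = 1e-6) -> tuple:
    """Bearing (radians, world frame) and magnitude of the stored home
    vector, read out from the CPU4 bump by folding the 16 cells into 8
    columns and extracting the fundamental's phase and amplitude.

    A flat memory (amplitude < ``eps``) returns ``(nan, 0.0)``.
    """
    folded = 0.5 * (state.cpu4[:N_COLUMNS] + state.cpu4[N_COLUMNS:])
    a = folded - folded.mean()
    z = complex(np.sum(a * np.exp(1j * _PHI)))
    magnitude = 2.0 * abs(z) / N_COLUMNS
    if magnitude < eps:
        return float("nan"), 0.0
    return wrap_angle(np.angle(z)), magnitude


def pi_closed_loop(headings, speeds, homing_ticks: int,
                   turn_rate: float = 0.08,
                   state: CXState | None = None) -> dict:
    """Outbound-then-homing path integration with point-agent kinematics.

    The CX integrates the commanded outbound route (per-tick heading and
    speed series), then closes the loop: each homing tick the steering
    output turns the heading by ``clip(theta, -1, 1) * turn_rate`` radians
    and the speed follows the step-length modulation (scaled so the cruise
    step length Sl=25 gives the outbound speed).  Returns the trajectory
    and the per-tick distance to the nest during homing.
    """
    cx = state or CXState()
    headings = np.asarray(headings, dtype=float)
    speeds = np.asarray(speeds, dtype=float)
    pos = np.zeros(2)
    outbound = [pos.copy()]
    for h, v in zip(headings, speeds):
        cx, _, _ = cx_pi_step(cx, h, v)
        pos = pos + v * np.array([math.cos(h), math.sin(h)])
        outbound.append(pos.copy())
    route_length = float(np.sum(speeds))

    h = float(headings[-1])
    v = float(speeds[-1])
    v_ref = float(speeds.mean())
    dists = []
    homing = []
    for _ in range(homing_ticks):
        cx, theta, sl = cx_pi_step(cx, h, v)
        h = wrap_angle(h + float(np.clip(theta, -1, 1)) * turn_rate)
        v = v_ref * sl / 25.0
        pos = pos + v * np.array([math.cos(h), math.sin(h)])
        homing.append(pos.copy())
        dists.append(float(np.linalg.norm(pos)))
    return {
        "outbound": np.array(outbound),
        "homing": np.array(homing),
        "distances": np.array(dists),
        "route_length": route_length,
        "min_distance": float(np.min(dists)) if dists else 0.0,
        "state": cx,
    }


# ---------------------------------------------------------------------------
# Steering circuit (shared by beacon and compass loops)
# ---------------------------------------------------------------------------

def steering_from_desired(current: np.ndarray, desired: np.ndarray,
                          k: float = 1.0) -> float:
    """CPU1-style comparison of a desired heading encoding against the
    current one: theta = k * (left-sum - right-sum).

    Positive output turns the body counter-clockwise (towards a desired
    heading CCW of the current one); equal encodings give exactly 0.
    """
    left = _clip01(np.roll(desired, 1) - current)
    right = _clip01(np.roll(desired, -1) - current)
    return k * float(left.sum() - right.sum())


# ---------------------------------------------------------------------------
# Visual beacon (copy-and-shift)
# ---------------------------------------------------------------------------

def beacon_desired_shift(left_mask: np.ndarray | None,
                         right_mask: np.ndarray | None,
                         mode: str, wvb: int | None = None,
                         delta_mode: str | None = None) -> tuple | None:
    """Column shift of the copy-and-shift mechanism from binarised eye
    masks.

    ``Pl`` is the mean column of landmark pixels per eye; ``delta`` is the
    offset of the visual centre from ``Pl`` (per-eye for monocular, averaged
    for binocular) and the integer shift is ceil(|6*delta/Wvb|) carrying
    delta's sign.  Returns ``(shift, sign)`` or None when the required
    mask(s) are empty (no detection; the caller keeps its previous command).
    """
    if mode not in ("left", "right", "binocular"):
        raise ValueError(f"unknown beacon mode: {mode!r}")
    if delta_mode is None:
        delta_mode = cfg.CONTROLLER_DEFAULTS["beacon_delta_mode"]

    def eye_delta(mask):
        if mask is None:
            return None
        mask = np.asarray(mask)
        xs = np.nonzero(mask)[-1]          # column indices of landmark pixels
        if xs.size == 0:
            return None
        w = mask.shape[-1] if wvb is None else wvb
        pl = float(xs.mean())
        centre = w / 2 if delta_mode == "center" else w
        return centre - pl, w

    deltas = {"left": eye_delta(left_mask), "right": eye_delta(right_mask)}
    if mode == "binocular":
        if deltas["left"] is None or deltas["right"] is None:
            return None
        delta = 0.5 * (deltas["left"][0] + deltas["right"][0])
        w = deltas["left"][1]
    else:
        if deltas[mode] is None:
            return None
        delta, w = deltas[mode]
    return shift_from_delta(delta, w)


def shift_from_delta(delta: float, wvb: int) -> tuple:
    """Integer copy-and-shift amount: ceil(|6*delta/Wvb|) with delta's sign."""
    shift = math.ceil(abs(6.0 * delta / wvb))
    sign = 0 if delta == 0 else int(math.copysign(1, delta))
    return shift, sign


def beacon_steering(shift_sign: tuple, heading: float,
                    k: float | None = None) -> float:
    """Turn command from a copy-and-shift result: the current heading ring
    is copied, shifted by ``shift`` columns towards the landmark side, and
    fed to the steering circuit as the desired heading."""
    if k is None:
        k = cfg.CONTROLLER_DEFAULTS["k_vb"]
    shift, sign = shift_sign
    desired = heading_encoding(heading + sign * shift * (2 * np.pi / N_COLUMNS))
    return steering_from_desired(heading_encoding(heading), desired, k)


# ---------------------------------------------------------------------------
# Zernike-moment visual compass
# ---------------------------------------------------------------------------

def _radial_poly(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    R = np.zeros_like(rho)
    for k in range((n - m) // 2 + 1):
        coef = ((-1) ** k * math.factorial(n - k)
                / (math.factorial(k)
                   * math.factorial((n + m) // 2 - k)
                   * math.factorial((n - m) // 2 - k)))
        R += coef * rho ** (n - 2 * k)
    return R


def zernike_moment(img: np.ndarray, n: int, m: int) -> complex:
    """Complex Zernike coefficient of a panoramic image on the unit disk.

    Columns map to the polar angle (2*pi*col/width) and rows to the radius
    ((row+0.5)/height, zenith at the disk centre); the standard basis
    (radial polynomial times complex exponential) is integrated against the
    image with the (n+1)/pi normalisation and the polar area element.
    A circular column shift of the image by c rotates the phase by exactly
    +m * 2*pi*c/ncols.
    """
    if m < 0 or n < m or (n - m) % 2:
        raise ValueError(f"invalid Zernike order/repetition: ({n}, {m})")
    img = np.asarray(img, dtype=float)
    rows, colums = img.shape
    rho = (np.arange(rows) + 0.5) / rows
    phi = 2 * np.pi * np.arange(colums) / colums
    Rn = _radial_poly(n, m, rho)
    radial_w = Rn * rho * (1.0 / rows)             # rho * d_rho
    ang = np.exp(1j * m * phi) * (2 * np.pi / colums)
    return complex((n + 1) / np.pi * (radial_w @ img @ ang))


@dataclass
class CompassMemory:
    """Stored phase of the Zernike coefficient at route start."""

    phase0: float                   # in (-pi, pi]
    magnitude0: float = 0.0
    n: int = cfg.CONTROLLER_DEFAULTS["zernike_n"]
    m: int = cfg.CONTROLLER_DEFAULTS["zernike_m"]

    @classmethod
    def from_image(cls, img: np.ndarray, n: int | None = None,
                   m: int | None = None) -> "CompassMemory":
        n = cfg.CONTROLLER_DEFAULTS["zernike_n"] if n is None else n
        m = cfg.CONTROLLER_DEFAULTS["zernike_m"] if m is None else m
        z = zernike_moment(img, n, m)
        return cls(phase0=wrap_angle(np.angle(z)), magnitude0=abs(z), n=n, m=m)


def visual_compass_step(img: np.ndarray, memory: CompassMemory,
                        eps: float | None = None) -> tuple | None:
    """Turn/step commands from the wrapped Zernike phase difference.

    theta = sign(delta) (sign(0) := 0) and Sl = |delta/5| with delta the
    wrapped phase difference in radians.  Returns None (hold the previous
    command) when the coefficient magnitude is below ``eps`` — a featureless
    panorama carries no direction.
    """
    if eps is None:
        eps = cfg.CONTROLLER_DEFAULTS["compass_min_magnitude"]
    z = zernike_moment(img, memory.n, memory.m)
    if abs(z) < eps:
        return None
    delta = wrap_angle(np.angle(z) - memory.phase0)
    theta = 0.0 if delta == 0 else math.copysign(1.0, delta)
    divisor = cfg.CONTROLLER_DEFAULTS["compass_divisor"]
    return theta, abs(delta) / divisor


# ---------------------------------------------------------------------------
# Odour trail following
# ---------------------------------------------------------------------------

def trail_follow_step(ol: float, orr: float, rng: np.random.Generator,
                      consts: dict | None = None) -> tuple:
    """Bilateral trail-following rule: ``(theta_cmd, Sl_deg)``.

    Odour is sensed iff max(Ol, Or) >= To.  On-trail and balanced
    (|Ol - Or| < Td) walk straight fast; unbalanced, steer by the
    difference scaled by kd; off-trail, turn randomly left or right with a
    short step (search).
    """
    c = consts or cfg.CONTROLLER_DEFAULTS
    od = ol - orr
    if max(ol, orr) >= c["trail_To"]:
        if abs(od) < c["trail_Td"]:
            return 0.0, c["trail_sl_on_deg"]
        return od / c["trail_kd"], c["trail_sl_edge_deg"]
    return float(rng.choice([-1.0, 1.0])), c["trail_sl_search_deg"]


# ---------------------------------------------------------------------------
# Odour plume tracking
# ---------------------------------------------------------------------------

@dataclass
class PlumeTrackerState:
    """Cast/orient/surge state machine; advanced once per gait loop."""

    mode: str = "search"                # search | orient | surge
    surge_count: int = 0                # completed surge loops (0..2)
    top: float = cfg.CONTROLLER_DEFAULTS["plume_Top"]
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))


def plume_track_step(state: PlumeTrackerState, ol: float, orr: float,
                     wl, wr, heading: float,
                     consts: dict | None = None) -> tuple:
    """One gait-loop decision of the plume tracker.

    Below the detection threshold the agent scans (random +-1 turn, small
    step).  Above it, the wind on the higher-concentration side defines the
    upwind bearing m = atan2(-wy, -wx); theta = sign of the wrapped error
    m - h, Sl = min(5 + |error mod 5|, 15) degrees (error in degrees), then
    the directive commands two straight surge loops at Sl=15 before the
    next sensory decision.  Returns ``(state, theta, Sl_deg, directive)``
    with directive in {"sense", "surge"}.
    """
    c = consts or cfg.CONTROLLER_DEFAULTS
    if state.mode == "surge" and state.surge_count < c["plume_surge_loops"]:
        state.surge_count += 1
        return state, 0.0, c["plume_sl_surge_deg"], (
            "surge" if state.surge_count < c["plume_surge_loops"] else "sense")

    if max(ol, orr) <= state.top:
        state.mode = "search"
        state.surge_count = 0
        theta = float(state.rng.choice([-1.0, 1.0]))
        return state, theta, c["plume_sl_search_deg"], "sense"

    wind = wl if ol >= orr else wr
    m = math.atan2(-float(wind[1]), -float(wind[0]))
    delta = wrap_angle(m - heading)
    delta_deg = math.degrees(delta)
    theta = 0.0 if delta_deg == 0 else math.copysign(1.0, delta_deg)
    sl = min(5.0 + abs(delta_deg) % 5.0, 15.0)
    state.mode = "surge"
    state.surge_count = 0
    return state, theta, sl, "surge"
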
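"""Synthetic visual worlds and embodied sensors.

Rendering is analytic silhouette ray-casting against geometric primitives:
landmarks are dark (default intensity 0) against a bright background
(default 255).  Two cameras are modelled: a spherical panoramic camera
(72x72, rows spanning zenith to nadir) used by the visual compass, and a
pair of planar pinhole eye cameras (74x19, horizontal FOV 2 rad, vertical
0.5 rad) used by the beacon controller.  Odour trails are a grayscale floor
texture sampled bilinearly under each antenna tip, scaled to a 0-1000
reflectance reading.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import config as cfg
from .body import KinematicModel, antenna_tip_body
from .locomotion import BodyPose

__all__ = [
    "Sphere", "Cylinder", "Cone", "Scene", "TrailMap", "AntennaState",
    "render_panorama", "render_binocular", "binarize_image",
    "trail_sensor_read", "antenna_sweep",
    "PANORAMA_SHAPE", "EYE_SHAPE", "EYE_FOV_H", "EYE_FOV_V",
]

PANORAMA_SHAPE = (72, 72)           # rows (elevation) x cols (azimuth)
EYE_SHAPE = (19, 74)                # rows x cols (Hvb=19, Wvb=74)
EYE_FOV_H = 2.0                     # radians
EYE_FOV_V = 0.5                     # radians


# ---------------------------------------------------------------------------
# Scene primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple
    radius: float
    intensity: float = 0.0

    def validate(self):
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")


@dataclass(frozen=True)
class Cylinder:
    """Vertical cylinder from z0 to z0+height."""

    center: tuple               # (x, y)
    radius: float
    height: float
    z0: float = 0.0
    intensity: float = 0.0

    def validate(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("cylinder radius and height must be positive")


@dataclass(frozen=True)
class Cone:
    """Vertical cone, base of radius `radius` at z0, apex at z0+height."""

    center: tuple
    radius: float
    height: float
    z0: float = 0.0
    intensity: float = 0.0

    def validate(self):
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("cone radius and height must be positive")


@dataclass
class Scene:
    """Visual world: landmark primitives over a uniform background, plus an
    optional floor trail texture and a world rotation angle (radians, about
    the world origin) used by the compass experiments."""

    primitives: list = field(default_factory=list)
    background: float = 255.0
    trail_map: "TrailMap | None" = None
    plume: object | None = None
    world_rotation: float = 0.0

    def __post_init__(self):
        if not 0 <= self.background <= 255:
            raise ValueError("background intensity must be in [0, 255]")
        for p in self.primitives:
            p.validate()
            if not 0 <= p.intensity <= 255:
                raise ValueError("primitive intensity must be in [0, 255]")

    def rotated_primitives(self) -> list:
        """Primitives with the world rotation applied about the origin."""
        w = self.world_rotation
        if w == 0.0:
            return list(self.primitives)
        c, s = math.cos(w), math.sin(w)

        def rot(p):
            x, y = p[0], p[1]
            return (c * x - s * y, s * x + c * y) + tuple(p[2:])

        out = []
        for p in self.primitives:
            out.append(replace(p, center=rot(p.center)))
        return out


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------

_EPS = 1e-9


def _hit_sphere(prim: Sphere, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    c = np.asarray(prim.center, dtype=float)
    oc = o - c
    b = d @ oc
    q = oc @ oc - prim.radius ** 2
    disc = b * b - q
    t = np.full(d.shape[0], np.inf)
    ok = disc >= 0
    root = np.sqrt(np.maximum(disc, 0.0))
    t1 = -b - root
    t2 = -b + root
    cand = np.where(t1 > _EPS, t1, np.where(t2 > _EPS, t2, np.inf))
    t[ok] = cand[ok]
    return t


def _hit_vertical_quadric(center, coef, z0, z1, o, d, apex_z=None):
    """Shared solver for cylinders/cones: (x-cx)^2+(y-cy)^2 = f(z)^2."""
    cx, cy = center
    ox, oy, oz = o
    dx, dy, dz = d[:, 0], d[:, 1], d[:, 2]
    px, py = ox - cx, oy - cy
    if apex_z is None:              # cylinder: radius constant
        a = dx * dx + dy * dy
        b = 2 * (px * dx + py * dy)
        cc = px * px + py * py - coef ** 2
    else:                           # cone: radius = coef*(apex_z - z)
        k2 = coef ** 2
        a = dx * dx + dy * dy - k2 * dz * dz
        g = apex_z - oz
        b = 2 * (px * dx + py * dy) + 2 * k2 * g * dz
        cc = px * px + py * py - k2 * g * g
    t_out = np.full(d.shape[0], np.inf)
    disc = b * b - 4 * a * cc
    ok = (disc >= 0) & (np.abs(a) > _EPS)
    root = np.sqrt(np.maximum(disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-b - root) / (2 * a)
        t2 = (-b + root) / (2 * a)
    for tc in (t1, t2):
        z = oz + tc * dz
        good = ok & (tc > _EPS) & (z >= z0) & (z <= z1) & (tc < t_out)
        t_out[good] = tc[good]
    return t_out


def _hit_primitive(prim, o: np.ndarray, d: np.ndarray) -> np.ndarray:
    if isinstance(prim, Sphere):
        return _hit_sphere(prim, o, d)
    if isinstance(prim, Cylinder):
        return _hit_vertical_quadric(prim.center, prim.radius, prim.z0,
                                     prim.z0 + prim.height, o, d)
    if isinstance(prim, Cone):
        slope = prim.radius / prim.height
        return _hit_vertical_quadric(prim.center, slope, prim.z0,
                                     prim.z0 + prim.height, o, d,
                                     apex_z=prim.z0 + prim.height)
    raise TypeError(f"unknown primitive type: {type(prim).__name__}")


def _cast(scene: Scene, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Nearest-hit intensity per ray (background where nothing is hit)."""
    n = dirs.shape[0]
    best_t = np.full(n, np.inf)
    img = np.full(n, float(scene.background))
    for prim in scene.rotated_primitives():
        t = _hit_primitive(prim, origin, dirs)
        closer = t < best_t
        best_t[closer] = t[closer]
        img[closer] = prim.intensity
    return img


# ---------------------------------------------------------------------------
# Cameras
# ---------------------------------------------------------------------------

def render_panorama(scene: Scene, pose: BodyPose,
                    eye_height: float | None = None,
                    shape: tuple = PANORAMA_SHAPE) -> np.ndarray:
    """Spherical panorama: rows span elevation (row 0 at the zenith),
    columns span azimuth CCW starting at the body heading."""
    if eye_height is None:
        eye_height = cfg.DEFAULT_BODY["panorama_height"] * cfg.DEFAULT_SCALE
    rows, colums = shape
    r = np.arange(rows)
    c = np.arange(colums)
    elev = np.pi / 2 - np.pi * (r + 0.5) / rows          # zenith -> nadir
    azim = pose.h + 2 * np.pi * c / colums
    E, A = np.meshgrid(elev, azim, indexing="ij")
    dirs = np.stack([np.cos(E) * np.cos(A), np.cos(E) * np.sin(A),
                     np.sin(E)], axis=-1).reshape(-1, 3)
    origin = np.array([pose.x, pose.y, eye_height])
    return _cast(scene, origin, dirs).reshape(shape)


def _eye_origin(pose: BodyPose, eye: str, body: dict) -> np.ndarray:
    side = 1.0 if eye == "left" else -1.0
    p = pose.body_to_world([body["eye_forward"],
                            side * body["eye_half_sep"], 0.0])
    return np.array([p[0], p[1], body["eye_height"]])


def render_binocular(scene: Scene, pose: BodyPose, eye: str,
                     body: dict | None = None,
                     toe_out_deg: float | None = None) -> np.ndarray:
    """Planar pinhole eye image (19 rows x 74 cols).

    Eyes sit at the sides of the head with their optical axes yawed
    outwards by ``toe_out_deg`` (lateral compound eyes; 0 gives parallel
    forward axes).  Columns increase to the right of the visual field; a
    landmark at CCW bearing phi from the optical axis lands near column
    Wvb/2 - f*tan(phi).
    """
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    if body is None:
        body = {k: v * cfg.DEFAULT_SCALE for k, v in cfg.DEFAULT_BODY.items()}
    if toe_out_deg is None:
        toe_out_deg = cfg.DEFAULT_EYE_TOE_OUT_DEG
    axis = pose.h + math.radians(toe_out_deg) * (1 if eye == "left" else -1)
    rows, colums = EYE_SHAPE
    fx = (colums / 2) / math.tan(EYE_FOV_H / 2)
    fy = (rows / 2) / math.tan(EYE_FOV_V / 2)
    fwd = np.array([math.cos(axis), math.sin(axis), 0.0])
    right = np.array([math.sin(axis), -math.cos(axis), 0.0])
    up = np.array([0.0, 0.0, 1.0])
    u = (np.arange(colums) + 0.5) - colums / 2
    v = (np.arange(rows) + 0.5) - rows / 2
    U, V = np.meshgrid(u, v)
    dirs = (fwd[None, None, :]
            + (U / fx)[..., None] * right[None, None, :]
            - (V / fy)[..., None] * up[None, None, :])
    dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
    origin = _eye_origin(pose, eye, body)
    return _cast(scene, origin, dirs.reshape(-1, 3)).reshape(EYE_SHAPE)


def binarize_image(img: np.ndarray, threshold: float,
                   background: float = 255.0) -> np.ndarray:
    """True where a pixel deviates from the background beyond ``threshold``
    (dark landmark pixels against a bright background)."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    return np.abs(np.asarray(img, dtype=float) - background) > threshold


# ---------------------------------------------------------------------------
# Trail map and antenna sensing
# ---------------------------------------------------------------------------

@dataclass
class TrailMap:
    """Grayscale floor texture (0-255) with a world-to-pixel transform.

    Pixel (iy, ix) covers world point (origin + (ix, iy)/resolution); the
    transform is invertible by construction (resolution > 0).
    """

    raster: np.ndarray              # (H, W), values 0..255
    origin: tuple                   # world coords of pixel (0, 0)
    resolution: float               # pixels per model unit

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=float)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    def world_to_pixel(self, x: float, y: float) -> tuple:
        return ((x - self.origin[0]) * self.resolution,
                (y - self.origin[1]) * self.resolution)

    def sample(self, x: float, y: float) -> float:
        """Bilinear sample at a world point; 0 outside the raster."""
        px, py = self.world_to_pixel(x, y)
        H, W = self.raster.shape
        if not (0 <= px <= W - 1 and 0 <= py <= H - 1):
            return 0.0
        ix, iy = int(min(px, W - 2)), int(min(py, H - 2))
        fx, fy = px - ix, py - iy
        r = self.raster
        return float((1 - fx) * (1 - fy) * r[iy, ix]
                     + fx * (1 - fy) * r[iy, ix + 1]
                     + (1 - fx) * fy * r[iy + 1, ix]
                     + fx * fy * r[iy + 1, ix + 1])

    def to_png(self, path) -> None:
        from PIL import Image
        Image.fromarray(np.clip(self.raster, 0, 255).astype(np.uint8)
                        ).save(path)

    @classmethod
    def from_png(cls, path, origin: tuple, resolution: float) -> "TrailMap":
        from PIL import Image
        raster = np.asarray(Image.open(path).convert("L"), dtype=float)
        return cls(raster=raster, origin=tuple(origin), resolution=resolution)


def trail_sensor_read(trail: TrailMap, tip_position) -> float:
    """Infra-red style reflectance reading (0-1000) under an antenna tip.

    The reading is the bilinear trail intensity under the tip's xy position,
    scaled so a saturated texel reads the full-scale 1000 (on-trail interior
    >= 900, background ~ 0)."""
    x, y = float(tip_position[0]), float(tip_position[1])
    return cfg.TRAIL_SENSOR_FULL_SCALE * trail.sample(x, y) / 255.0


@dataclass(frozen=True)
class AntennaState:
    """Sweep configuration of the two antennae."""

    mode: str = "moving"                        # "fixed" | "moving"
    amplitude_deg: float = cfg.DEFAULT_ANTENNA_SWEEP["amplitude_deg"]
    period_ticks: int = cfg.DEFAULT_ANTENNA_SWEEP["period_ticks"]
    phase: int = 0
    rest_deg: tuple = cfg.DEFAULT_ANTENNA_REST_DEG

    def __post_init__(self):
        if self.mode not in ("fixed", "moving"):
            raise ValueError("mode must be 'fixed' or 'moving'")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be >= 0")
        if self.period_ticks < 2:
            raise ValueError("period must be >= 2 ticks")


def antenna_sweep(state: AntennaState, tick: int) -> dict:
    """Per-antenna joint angles (degrees) at a tick.

    Fixed mode holds the rest angles; moving mode oscillates the lateral
    (z-axis) joint sinusoidally, the two antennae in antiphase."""
    rest = state.rest_deg
    if state.mode == "fixed":
        return {"AL": tuple(rest), "AR": tuple(rest)}
    s = math.sin(2 * math.pi * (tick + state.phase) / state.period_ticks)
    dl = state.amplitude_deg * s
    return {"AL": (rest[0] + dl, rest[1], rest[2]),
            "AR": (rest[0] - dl, rest[1], rest[2])}


def save_image(img: np.ndarray, path) -> None:
    """Dump a rendered sensor image (0-255 intensities) as grayscale PNG."""
    from PIL import Image
    Image.fromarray(np.clip(np.asarray(img), 0, 255).astype(np.uint8)
                    ).save(path)


def antenna_tips_world(model: KinematicModel, pose: BodyPose,
                       angles: dict) -> dict:
    """World xy(z) positions of both antenna tips for given joint angles."""
    out = {}
    for ant in cfg.ANTENNA_IDS:
        tip_body = antenna_tip_body(model, ant, angles[ant])
        out[ant] = pose.body_to_world(tip_body)
    return out
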
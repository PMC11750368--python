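"""Filament-based odour plume and wind simulation.

Odour is carried by discrete Gaussian puffs released at a source and
advected by a mean wind plus coloured (first-order autoregressive) noise;
each puff's squared radius grows linearly with time, and a small
"centreline" relative-dispersion noise jitters individual puffs so that the
instantaneous plume is patchy while the time-averaged concentration stays
centred on the downwind axis.  Concentration at a point is the superposition
of normalised 3-D Gaussian kernels:

    C(p) = sum_i  q * (2*pi*s_i)^(-3/2) * exp(-|p - p_i|^2 / (2*s_i))

with s_i the puff's squared radius.  A planar agent samples the 3-D field at
its antenna height.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["Puff", "PlumeParams", "PlumeState", "plume_init", "plume_step",
           "concentration_at", "wind_at"]


@dataclass
class Puff:
    position: np.ndarray        # 3-vector, model units
    s: float                    # squared radius, model units^2
    q: float                    # release strength (constant)


@dataclass(frozen=True)
class PlumeParams:
    """Plume/wind model parameters (distances in model units, time in ticks).

    Defaults put the source at the origin with a gentle +x wind; they are
    sized so a walking agent a few body lengths downwind receives an
    intermittent but trackable signal.
    """

    source: tuple = (0.0, 0.0, 0.25)
    release_rate: float = 0.2           # puffs per tick
    puff_strength: float = 1.0
    puff_init_s: float = 0.0025         # initial squared radius
    puff_growth: float = 4e-5           # ds/dt per tick
    mean_wind: tuple = (0.015, 0.0)     # model units per tick
    wind_noise_std: float = 0.002       # stationary std of the AR(1) noise
    wind_noise_corr: float = 0.95       # AR(1) coefficient per tick
    centerline_dispersion: float = 0.003  # per-puff jitter std per tick
    vertical_dispersion: float = 0.0005
    spatial_noise_mag: float = 0.001    # point-to-point wind variation
    spatial_noise_wavelength: float = 1.0
    bounds: tuple = ((-0.5, 5.0), (-2.0, 2.0), (0.0, 1.0))

    def validate(self) -> None:
        if self.release_rate < 0:
            raise ValueError("release_rate must be >= 0")
        if self.puff_growth <= 0:
            raise ValueError("puff_growth must be > 0")
        if self.puff_init_s <= 0:
            raise ValueError("puff_init_s must be > 0")
        if self.puff_strength <= 0:
            raise ValueError("puff_strength must be > 0")
        if not 0 <= self.wind_noise_corr < 1:
            raise ValueError("wind_noise_corr must be in [0, 1)")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError("domain bounds must be well-ordered")


@dataclass
class PlumeState:
    params: PlumeParams
    puffs: list = field(default_factory=list)
    wind_noise: np.ndarray = field(default_factory=lambda: np.zeros(2))
    tick: int = 0
    released: int = 0
    culled: int = 0
    _release_accum: float = 0.0
    rng: np.random.Generator = field(
        default_factory=lambda: np.random.default_rng(0))

    @property
    def live_count(self) -> int:
        return len(self.puffs)


def plume_init(params: PlumeParams, seed: int) -> PlumeState:
    """Fresh plume state with a deterministic RNG; no puffs before tick 1."""
    params.validate()
    return PlumeState(params=params, rng=np.random.default_rng(seed))


def plume_step(state: PlumeState, dt: float = 1.0) -> PlumeState:
    """Advance the plume by ``dt`` ticks (in place; returns the state).

    Releases ``rate*dt`` puffs (fractional remainder carried over), advects
    every puff by the local wind plus centreline-dispersion jitter, grows
    the squared radii, culls puffs leaving the domain, and advances the
    coloured-noise wind state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = state.params
    rng = state.rng

    # wind coloured-noise recursion (stationary std = wind_noise_std)
    rho = p.wind_noise_corr
    if p.wind_noise_std > 0:
        innov = rng.normal(0.0, p.wind_noise_std * math.sqrt(1 - rho * rho),
                           size=2)
    else:
        innov = np.zeros(2)
    state.wind_noise = rho * state.wind_noise + innov
    wind = np.array([p.mean_wind[0] + state.wind_noise[0],
                     p.mean_wind[1] + state.wind_noise[1], 0.0])

    # release
    state._release_accum += p.release_rate * dt
    n_new = int(state._release_accum)
    state._release_accum -= n_new
    for _ in range(n_new):
        state.puffs.append(Puff(position=np.array(p.source, dtype=float),
                                s=p.puff_init_s, q=p.puff_strength))
    state.released += n_new

    # advect, jitter, grow
    survivors = []
    (x0, x1), (y0, y1), (z0, z1) = p.bounds
    for puff in state.puffs:
        jitter = np.array([
            rng.normal(0.0, p.centerline_dispersion),
            rng.normal(0.0, p.centerline_dispersion),
            rng.normal(0.0, p.vertical_dispersion),
        ]) if p.centerline_dispersion > 0 or p.vertical_dispersion > 0 \
            else np.zeros(3)
        puff.position = puff.position + wind * dt + jitter * math.sqrt(dt)
        puff.s += p.puff_growth * dt
        x, y, z = puff.position
        if x0 <= x <= x1 and y0 <= y <= y1 and z0 <= z <= z1:
            survivors.append(puff)
        else:
            state.culled += 1
    state.puffs = survivors
    state.tick += 1
    return state


def concentration_at(state: PlumeState, point) -> float:
    """Superposed Gaussian-kernel concentration at a 3-D point (>= 0)."""
    if not state.puffs:
        return 0.0
    p = np.asarray(point, dtype=float)
    pos = np.array([puff.position for puff in state.puffs])
    s = np.array([puff.s for puff in state.puffs])
    q = np.array([puff.q for puff in state.puffs])
    d2 = np.sum((pos - p) ** 2, axis=1)
    return float(np.sum(q * (2 * np.pi * s) ** -1.5 * np.exp(-d2 / (2 * s))))


def puffs_to_frame(state: PlumeState):
    """Live puff list as a (tick, x, y, z, s, q) table for CSV dumps."""
    import pandas as pd

    rows = [(state.tick, *puff.position, puff.s, puff.q)
            for puff in state.puffs]
    return pd.DataFrame(rows, columns=["tick", "x", "y", "z", "s", "q"])


def wind_at(state: PlumeState, point) -> np.ndarray:
    """Wind vector (wx, wy) at a point: mean wind + coloured-noise state +
    a small smoothly-varying spatial perturbation."""
    p = state.params
    w = np.array([p.mean_wind[0] + state.wind_noise[0],
                  p.mean_wind[1] + state.wind_noise[1]])
    if p.spatial_noise_mag > 0:
        k = 2 * math.pi / p.spatial_noise_wavelength
        phase = 0.37 * state.tick
        w = w + p.spatial_noise_mag * np.array([
            math.sin(k * float(point[0]) + phase),
            math.sin(k * float(point[1]) - phase),
        ])
    return w
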
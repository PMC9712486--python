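"""Area-concentrated search (ACS) movement kernel.

Movement is a state-dependent correlated random walk: each step an individual
turns by an angle drawn from a wrapped normal distribution with mean 0 and a
standard deviation ``d`` that depends on its searching time ``ΔS`` — the
number of consecutive steps since it last captured a resource item:

    d(ΔS) = d_min + (d_max − d_min) · (1 − ΔS^α / (ΔS^α + h^α))

Immediately after a find (ΔS = 0) the turn SD is ``d_max`` and the path is
highly tortuous (area-concentrated search); as ΔS grows past the
half-saturation constant ``h`` the SD decays toward ``d_min`` and movement
straightens into near-ballistic search.  Two limiting modes are obtained by
moving ``h`` to its extremes: ``h = 0`` yields unconditional straight-line
movement (SLM, constant ``d_min``) and a very large ``h`` (10,000) yields a
plain correlated random walk (CRW, SD pinned near ``d_max``).

Step length ``p`` is constant; after turning, the individual advances ``p``
units along its heading and is torus-wrapped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .landscape import torus_wrap

__all__ = [
    "MovementParams",
    "IndividualState",
    "turning_sd",
    "draw_turn",
    "advance",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class MovementParams:
    """ACS kernel constants.

    d_min, d_max : float
        Bounds of the turning-angle SD in radians (defaults 0.01 and 1).
    alpha : float
        Shape exponent of the saturation curve (default 3).
    h : float
        Half-saturation constant in steps (default 200); 0 selects SLM,
        10,000 approximates a CRW.
    p : float
        Step length, spatial units (default 1).
    c : float
        Perception radius, spatial units (default 1).
    """

    d_min: float = 0.01
    d_max: float = 1.0
    alpha: float = 3.0
    h: float = 200.0
    p: float = 1.0
    c: float = 1.0

    def __post_init__(self):
        if not (0 < self.d_min <= self.d_max):
            raise ValueError("require 0 < d_min <= d_max")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.p <= 0 or self.c <= 0:
            raise ValueError("p and c must be positive")

    @classmethod
    def acs(cls, **kw) -> "MovementParams":
        return cls(**kw)

    @classmethod
    def slm(cls, **kw) -> "MovementParams":
        """Straight-line movement: h = 0, turn SD constantly d_min."""
        return cls(h=0.0, **kw)

    @classmethod
    def crw(cls, **kw) -> "MovementParams":
        """Simple correlated random walk: h = 10,000, turn SD near d_max."""
        return cls(h=10_000.0, **kw)


@dataclass
class IndividualState:
    """Position, heading and searching time of one individual."""

    position: np.ndarray  # (2,), in [0, L)^2
    heading: float  # radians, [0, 2π)
    delta_s: int  # steps since last resource capture

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.heading = float(self.heading) % TWO_PI
        if self.delta_s < 0:
            raise ValueError("delta_s must be >= 0")


def turning_sd(delta_s, params: MovementParams):
    """Turning-angle SD (radians) as a function of searching time.

    Vectorized over ``delta_s``; the result is bounded in
    ``[d_min, d_max]`` and non-increasing in ``delta_s``.  ``h = 0`` is the
    SLM limit and returns ``d_min`` for every ΔS (avoiding the 0/0 at
    ΔS = 0).
    """
    ds = np.asarray(delta_s, dtype=float)
    if np.any(ds < 0):
        raise ValueError("delta_s must be >= 0")
    if params.h == 0:
        out = np.full(ds.shape, params.d_min)
        return float(out) if out.ndim == 0 else out
    dsa = ds ** params.alpha
    denom = dsa + params.h ** params.alpha
    # h^alpha can underflow to 0 for tiny h; at delta_s = 0 that leaves 0/0,
    # whose h -> 0+ limit is 0 (the d_max end of the curve)
    with np.errstate(invalid="ignore"):
        frac = np.where(denom > 0, dsa / np.where(denom > 0, denom, 1.0), 0.0)
    out = params.d_min + (params.d_max - params.d_min) * (1.0 - frac)
    return float(out) if out.ndim == 0 else out


def wrap_angle(angle):
    """Wrap angle(s) into (−π, π]."""
    w = np.remainder(np.asarray(angle, dtype=float), TWO_PI)
    w = np.where(w > np.pi, w - TWO_PI, w)
    return float(w) if w.ndim == 0 else w


def draw_turn(sd, rng: np.random.Generator, size=None):
    """Draw turning angle(s) from a wrapped normal(0, sd) into (−π, π].

    ``sd`` may be a scalar or an array broadcastable against ``size``; for
    the SDs used here (≤ 1 rad) the wrapped probability mass is negligible
    but wrapping is always applied.
    """
    sd_arr = np.asarray(sd, dtype=float)
    if np.any(sd_arr <= 0):
        raise ValueError("sd must be positive")
    raw = rng.normal(0.0, sd_arr, size=size)
    return wrap_angle(raw)


def advance(
    state: IndividualState,
    params: MovementParams,
    L: float,
    rng: np.random.Generator,
) -> IndividualState:
    """One movement step: turn, then advance ``p`` units; ΔS is untouched.

    The searching-time update belongs to the foraging loop (it depends on
    the harvest outcome at the new position), so ``delta_s`` is carried over
    unchanged.
    """
    turn = draw_turn(turning_sd(state.delta_s, params), rng)
    heading = (state.heading + turn) % TWO_PI
    step = params.p * np.array([math.cos(heading), math.sin(heading)])
    position = torus_wrap(state.position + step, L)
    return IndividualState(position=position, heading=heading, delta_s=state.delta_s)
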
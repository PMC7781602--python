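"""Closed-form asymptotic wave speeds and comoving concentration profiles.

In the comoving frame r_tilde = r - v t (negative inside the wave front),
the relay admits traveling-wave solutions whose speed depends on the pair
(cell dimension, diffusion dimension) only through the dimension mismatch:

    matched dims (thin medium / channel):  v = sqrt(a rho D / (h^k Cth))
    one-dimension mismatch (semi-infinite): v = 2 a rho / (pi h^k Cth)

with k the number of confined directions (0, 1 or 2).  In the mismatched
case the speed carries no D whatsoever: a wave driven by diffusion whose
speed is independent of the rate of diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import Geometry, PhysicalParams

#: dimensionless speed prefactor for the semi-infinite (mismatched) case,
#: exact for Heaviside activation and approximately valid for Hill orders >= 2
ALPHA_THICK = 2.0 / np.pi


def wave_speed(params: PhysicalParams, geom: Geometry) -> float:
    """Asymptotic relay wave speed (m/s) for the given geometry.

    (1,1): sqrt(a rho D / (h^2 Cth))   — channel of cross-section h x h
    (2,2): sqrt(a rho D / (h Cth))     — film of thickness h
    (3,3): sqrt(a rho D / Cth)
    (1,2): 2 a rho / (pi h Cth)        — semi-infinite half-plane, film h
    (2,3): 2 a rho / (pi Cth)          — semi-infinite half-space
    """
    D, a, rho, Cth = params.D, params.a, params.rho, params.Cth
    pair = geom.pair
    if pair == (1, 1):
        h = params.require_thickness(geom)
        return float(np.sqrt(a * rho * D / (h ** 2 * Cth)))
    if pair == (2, 2):
        h = params.require_thickness(geom)
        return float(np.sqrt(a * rho * D / (h * Cth)))
    if pair == (3, 3):
        return float(np.sqrt(a * rho * D / Cth))
    if pair == (1, 2):
        h = params.require_thickness(geom)
        return float(2 * a * rho / (np.pi * h * Cth))
    if pair == (2, 3):
        return float(2 * a * rho / (np.pi * Cth))
    raise ValueError(f"unsupported geometry {pair}")  # pragma: no cover


def profile_thin(r_tilde, params: PhysicalParams,
                 geom: Geometry = Geometry(2, 2)) -> np.ndarray:
    """Comoving concentration profile for a thin medium (matched dims).

    Linear growth inside the front, exponential decay beyond::

        c(rt) = Cth * (1 - rt v / D)     rt <= 0
        c(rt) = Cth * exp(-rt v / D)     rt >= 0

    with Cth = a rho D / (h^k v^2).  Continuous with continuous first
    derivative at rt = 0; c(0) = Cth exactly.
    """
    if not geom.matched:
        raise ValueError("profile_thin applies to matched-dimension media")
    v = wave_speed(params, geom)
    rt = np.asarray(r_tilde, dtype=float)
    x = rt * v / params.D
    return params.Cth * np.where(x <= 0, 1.0 - x, np.exp(-np.minimum(x, 700)))


@dataclass(frozen=True)
class ThickProfile:
    """Asymptotic thick-medium profile evaluated at the cell plane.

    ``value`` is the concentration; ``reliable`` is False in the crossover
    zone |r_tilde| <~ D/v where the two printed limits do not apply and no
    closed form exists.
    """

    value: np.ndarray
    reliable: np.ndarray


def profile_thick(r_tilde, params: PhysicalParams,
                  crossover: float = 1.0) -> ThickProfile:
    """Comoving in-plane profile for cells in 2D under a semi-infinite medium.

    Square-root growth inside the front, exponentially damped tail outside::

        c(rt) = 2 a rho sqrt(-rt / (pi v D))            rt << -D/v
        c(rt) = a rho sqrt(D / (pi rt v^3)) e^(-v rt/D)  rt >> +D/v

    Only the two limits are known in closed form; points with
    |rt| < crossover * D/v are flagged unreliable rather than interpolated.
    """
    v = wave_speed(params, Geometry(2, 3))
    a_rho = params.a * params.rho
    D = params.D
    rt = np.atleast_1d(np.asarray(r_tilde, dtype=float))
    c = np.empty_like(rt)
    inside = rt < 0
    c[inside] = 2 * a_rho * np.sqrt(-rt[inside] / (np.pi * v * D))
    out = ~inside
    with np.errstate(divide="ignore", invalid="ignore"):
        c[out] = (a_rho * np.sqrt(D / (np.pi * rt[out] * v ** 3))
                  * np.exp(-np.minimum(v * rt[out] / D, 700)))
    c[rt == 0] = params.Cth          # threshold anchors the front
    reliable = np.abs(rt) * v / D >= crossover
    return ThickProfile(value=c, reliable=reliable)


@dataclass(frozen=True)
class AsymptoticWave:
    """Speed, prefactor and comoving profile of the asymptotic wave."""

    v: float
    alpha: float
    profile: Callable[[np.ndarray], np.ndarray]


def asymptotic_wave(params: PhysicalParams, geom: Geometry) -> AsymptoticWave:
    v = wave_speed(params, geom)
    if geom.matched:
        return AsymptoticWave(
            v=v, alpha=1.0, profile=lambda rt: profile_thin(rt, params, geom))
    if geom.pair == (2, 3):
        return AsymptoticWave(
            v=v, alpha=ALPHA_THICK,
            profile=lambda rt: profile_thick(rt, params).value)
    # (1,2): same mismatch class; in-plane profile shares the (2,3) form
    return AsymptoticWave(v=v, alpha=ALPHA_THICK, profile=None)
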
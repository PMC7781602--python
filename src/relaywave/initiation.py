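"""Wave-initiation times and critical colony sizes.

A colony of radius ri emits continuously from t = 0; the wave initiates at
the time t_init when the concentration at the colony edge first reaches
Cth and the surrounding cells join the relay.  In 1D and 2D diffusive
environments the concentration grows without bound, so every colony
eventually initiates (though for ri << D/v the wait can exceed D/v^2 by
orders of magnitude).  In 3D environments the colony concentration
saturates at a finite steady state, so there is a critical radius below
which no wave ever launches: ri = D/v for cells in 2D, ri = sqrt(3) D/v
for cells in 3D (from the uniformly emitting ball, c_ss(ri) = a rho ri^2 / 3D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from . import greens
from .params import Geometry, PhysicalParams
from .greens import DEFAULT_QUAD, QuadratureOptions

#: 3D environments, where a steady state exists and initiation can fail
_SATURATING = {(2, 3), (3, 3)}


@dataclass(frozen=True)
class InitiationResult:
    initiated: bool
    ri: float
    geometry: Geometry
    t_init: Optional[float] = None      # s, present iff initiated
    regime: str = "crossover"           # small_colony/crossover/plateau/below_critical

    def __post_init__(self) -> None:
        if self.initiated and not (self.t_init and self.t_init > 0):
            raise ValueError("initiated results carry t_init > 0")


def _classify(ri_nd: float) -> str:
    # package convention: boundaries of the closed-form limits' usefulness
    if ri_nd < 0.5:
        return "small_colony"
    if ri_nd > 5.0:
        return "plateau"
    return "crossover"


def initiation_time(ri: float, params: PhysicalParams, geom: Geometry,
                    t_max: float = math.inf, rtol: float = 1e-4,
                    opts: QuadratureOptions = DEFAULT_QUAD) -> InitiationResult:
    """Solve Cth = c(ri, t) for the initiation time of a colony of radius ri.

    The colony concentration is monotone increasing in t, so the root is
    bracketed by doubling from t = D/100 v^2 and then polished.  In 3D
    environments "never initiates" is decided against the steady state
    rather than a finite horizon, which avoids false negatives from slow
    saturation; in 1D/2D environments a finite ``t_max`` hit raises
    instead, because initiation is only a matter of waiting longer.
    """
    if ri <= 0:
        raise ValueError("ri must be > 0")
    from . import asymptotics
    v = asymptotics.wave_speed(params, geom)
    L, T = params.D / v, params.D / v ** 2
    ri_nd = ri / L
    pair = geom.pair

    if pair in _SATURATING:
        css = greens.steady_state_nd(pair, ri_nd, ri_nd, opts)
        if css <= 1.0:
            return InitiationResult(False, ri, geom, regime="below_critical")

    def deficit(t_nd: float) -> float:
        return greens.colony_concentration_nd(pair, ri_nd, t_nd, ri_nd, opts) - 1.0

    t_lo, t_hi = 0.0, 0.01
    f_hi = deficit(t_hi)
    while f_hi < 0:
        t_lo, t_hi = t_hi, 2 * t_hi
        if t_hi * T > t_max:
            if pair in _SATURATING:
                # steady state says it initiates; keep looking is safe but
                # the caller capped us
                raise RuntimeError(
                    f"t_max={t_max} s reached before initiation; the steady "
                    f"state does exceed Cth, so increase t_max")
            raise RuntimeError(
                f"t_max={t_max} s reached; 1D/2D environments always "
                f"initiate — increase t_max")
        f_hi = deficit(t_hi)
    t_nd = optimize.brentq(deficit, t_lo if t_lo > 0 else t_hi / 4, t_hi,
                           rtol=rtol)
    return InitiationResult(True, ri, geom, t_init=float(t_nd * T),
                            regime=_classify(ri_nd))


def critical_radius(params: PhysicalParams, geom: Geometry,
                    rtol: float = 1e-6,
                    opts: QuadratureOptions = DEFAULT_QUAD) -> Optional[float]:
    """Smallest initiating colony radius, or None where waves always initiate.

    Defined only in 3D diffusive environments, as the radius whose
    steady-state edge concentration equals Cth (bisection on ri against the
    dedicated steady-state quadrature).
    """
    if geom.pair not in _SATURATING:
        return None
    from . import asymptotics
    v = asymptotics.wave_speed(params, geom)
    L = params.D / v

    def excess(ri_nd: float) -> float:
        return greens.steady_state_nd(geom.pair, ri_nd, ri_nd, opts) - 1.0

    lo, hi = 1e-3, 1.0
    while excess(hi) < 0:
        lo, hi = hi, 2 * hi
        if hi > 1e3:  # pragma: no cover - unreachable for supported pairs
            raise RuntimeError("failed to bracket the critical radius")
    ri_nd = optimize.brentq(excess, lo, hi, rtol=rtol)
    return float(ri_nd * L)


def tinit_asymptotic(ri: float, params: PhysicalParams, geom: Geometry,
                     regime: str = "auto") -> Optional[float]:
    """Closed-form initiation-time limits, for cross-validation only.

    Small-colony branches (ri << D/v):
        (1,1):  (pi D / 4 v^2) (D / v ri)^2
        (2,2):  ~ (ri^2 / 4D) exp[(2D / v ri)^2]        (order of magnitude)
        (1,2):  ~ exp[(2D / v ri)^2]                    (exponent only)
    Large-colony plateaus (ri >> D/v): 2 D/v^2 for matched dimensions,
    4 D / pi v^2 for mismatched.  Cells in 3D diverge near the critical
    radius as (D/9 pi v^2) (v ri/D)^6 [(v ri)^2/(3 D^2) - 1]^(-2) and do
    not initiate below sqrt(3) D/v; cells in 2D under 3D diffusion do not
    initiate below D/v (no small-colony law).

    Returns None where no tabulated limit applies.  ``regime`` may force
    'small', 'plateau' or 'near_critical' instead of the ri-based choice.
    """
    from . import asymptotics
    v = asymptotics.wave_speed(params, geom)
    D = params.D
    x = v * ri / D  # ri in units of D/v
    T = D / v ** 2
    pair = geom.pair
    plateau = 2.0 * T if geom.matched else 4.0 * T / np.pi

    if regime == "auto":
        if pair == (3, 3):
            if x <= math.sqrt(3):
                return None
            regime = "near_critical" if x < 2 * math.sqrt(3) else "plateau"
        elif x < 1.0:
            regime = "small"
        elif x > 3.0:
            regime = "plateau"
        else:
            return None

    if regime == "plateau":
        return plateau
    if regime == "near_critical":
        if pair != (3, 3):
            raise ValueError("near_critical regime applies to (3,3) only")
        bracket = x * x / 3.0 - 1.0
        if bracket <= 0:
            return None
        return float(T / (9 * np.pi) * x ** 6 / bracket ** 2)
    if regime == "small":
        if pair == (1, 1):
            return float(np.pi * T / 4 / x ** 2)
        if pair == (2, 2):
            return float(ri ** 2 / (4 * D) * np.exp((2.0 / x) ** 2))
        if pair == (1, 2):
            return float(np.exp((2.0 / x) ** 2))   # prefactor unknown
        return None  # 3D environments: no waves from small colonies
    raise ValueError(f"unknown regime {regime!r}")
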
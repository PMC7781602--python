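"""Self-consistent propagation of the information front r_c(t).

The information front is the curve along which the concentration equals
the activation threshold: Cth = c(r_c(t), t), with every radius below
max(ri, r_c(T)) emitting at past times T.  The front is found on a time
grid of step dt (default D/10 v^2), root-solving at each step for the
radius at which the accumulated Green's-function integral over the entire
emission history equals Cth; linear interpolation between grid points
defines the continuous curve.  The unknown current-step segment is included
in the history at its candidate value inside the root solve, so the
self-consistency constraint holds exactly at every accepted point.

The simple-diffusion comparison model truncates the emitting region at the
initial colony ri at all times — only the target cells ever signal — and
its front is the threshold level set of that colony field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from . import greens
from .greens import DEFAULT_QUAD, QuadratureOptions
from .params import Geometry, PhysicalParams

DEFAULT_DT_ND = 0.1   # Delta t = D / 10 v^2


@dataclass(frozen=True)
class FrontTrajectory:
    """Discretized information front r_c(t) with linear interpolation.

    ``times`` are strictly increasing (s); ``radii`` the front radius (m).
    For the relay model the first grid point is (t_init, ri).  A
    simple-diffusion trajectory may be empty (threshold never reached).
    """

    times: np.ndarray
    radii: np.ndarray
    ri: float
    dt: float
    model: str = "relay"              # 'relay' | 'simple_diffusion'
    geometry: Optional[Geometry] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "radii", np.asarray(self.radii, float))
        if self.times.size != self.radii.size:
            raise ValueError("times and radii must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def radius_at(self, t):
        """Linear interpolation of r_c; ri before t_start, clamped at ends."""
        if len(self) == 0:
            raise ValueError("empty trajectory")
        t = np.asarray(t, float)
        out = np.interp(t, self.times, self.radii)
        return np.where(t < self.times[0], self.ri, out)

    __call__ = radius_at


def propagate_front(params: PhysicalParams, geom: Geometry, ri: float,
                    t_end: float, dt: Optional[float] = None,
                    opts: QuadratureOptions = DEFAULT_QUAD,
                    rtol: float = 1e-5) -> FrontTrajectory:
    """Propagate the relay information front from initiation to t_end.

    Raises if the wave does not initiate (3D environments below the
    critical colony size) — see the initiation module.  Concentration is
    monotone decreasing in r beyond the emitting region, so each step has a
    unique root; the bracket starts at [r_prev, r_prev + 10 v dt] and
    expands outward if needed.
    """
    from . import asymptotics, initiation

    v = asymptotics.wave_speed(params, geom)
    L, T = params.D / v, params.D / v ** 2
    res = initiation.initiation_time(ri, params, geom, opts=opts)
    if not res.initiated:
        raise RuntimeError(
            f"wave does not initiate for ri={ri} m in geometry {geom.pair}; "
            f"the critical radius is "
            f"{initiation.critical_radius(params, geom)} m")
    dt_nd = DEFAULT_DT_ND if dt is None else dt / T
    t0 = res.t_init / T
    t_end_nd = t_end / T
    ri_nd = ri / L
    pair = geom.pair

    n = max(int(np.ceil((t_end_nd - t0) / dt_nd)), 1)
    times = t0 + dt_nd * np.arange(n + 1)
    radii = np.empty(n + 1)
    radii[0] = ri_nd
    for k in range(1, n + 1):
        t = times[k]

        def excess(r: float) -> float:
            radii[k] = r   # candidate point participates in its own history
            return greens.front_concentration_nd(
                pair, r, t, times[:k + 1], radii[:k + 1], ri_nd, opts) - 1.0

        lo = radii[k - 1]
        hi = lo + 10 * dt_nd
        f_hi = excess(hi)
        while f_hi > 0:
            lo = hi
            hi += 10 * dt_nd
            f_hi = excess(hi)
        radii[k] = optimize.brentq(excess, lo, hi, xtol=rtol)
    return FrontTrajectory(times=times * T, radii=radii * L, ri=ri,
                           dt=dt_nd * T, model="relay", geometry=geom)


def simple_diffusion_front(params: PhysicalParams, geom: Geometry, ri: float,
                           t_end: float, dt: Optional[float] = None,
                           opts: QuadratureOptions = DEFAULT_QUAD,
                           rtol: float = 1e-5) -> FrontTrajectory:
    """Threshold level set when only the target colony ever emits.

    The trajectory is empty before the colony field first reaches Cth at
    ri, and — in 3D environments — remains empty altogether if the steady
    state never reaches Cth.  For a 3D environment the front approaches a
    finite limiting radius; in 1D/2D it advances like sqrt(t) at late
    times (up to logs), always decelerating.
    """
    from . import asymptotics, initiation

    v = asymptotics.wave_speed(params, geom)
    L, T = params.D / v, params.D / v ** 2
    pair = geom.pair
    # level-set points are independent of each other (no emission history),
    # so the grid only controls interpolation accuracy: cap it at 400 steps
    if dt is None:
        dt_nd = max(DEFAULT_DT_ND, (t_end / T) / 400)
    else:
        dt_nd = dt / T
    ri_nd, t_end_nd = ri / L, t_end / T

    try:
        res = initiation.initiation_time(ri, params, geom, opts=opts)
    except RuntimeError:
        res = None
    if res is None or not res.initiated:
        return FrontTrajectory(times=np.empty(0), radii=np.empty(0), ri=ri,
                               dt=dt_nd * T, model="simple_diffusion",
                               geometry=geom)
    t0 = res.t_init / T
    if t0 >= t_end_nd:
        return FrontTrajectory(times=np.empty(0), radii=np.empty(0), ri=ri,
                               dt=dt_nd * T, model="simple_diffusion",
                               geometry=geom)

    n = max(int(np.ceil((t_end_nd - t0) / dt_nd)), 1)
    times = t0 + dt_nd * np.arange(n + 1)
    radii = np.empty(n + 1)
    radii[0] = ri_nd
    prev = ri_nd
    for k in range(1, n + 1):
        t = times[k]

        def excess(r: float) -> float:
            return greens.colony_concentration_nd(pair, r, t, ri_nd, opts) - 1.0

        lo, hi = prev, prev + 10 * dt_nd
        f_lo = excess(lo)
        if f_lo < 0:   # the level set can recede only through numerics; guard
            lo = ri_nd
        f_hi = excess(hi)
        while f_hi > 0:
            lo, hi = hi, hi + 10 * dt_nd
            f_hi = excess(hi)
        radii[k] = optimize.brentq(excess, lo, hi, xtol=rtol)
        prev = radii[k]
    return FrontTrajectory(times=times * T, radii=radii * L, ri=ri,
                           dt=dt_nd * T, model="simple_diffusion",
                           geometry=geom)


def estimate_speed(front: FrontTrajectory, window: tuple[float, float]) -> float:
    """Least-squares slope of r_c(t) over the time window (m/s)."""
    t0, t1 = window
    m = (front.times >= t0) & (front.times <= t1)
    if m.sum() < 5:
        raise ValueError(
            f"window {window} contains {int(m.sum())} grid points; >= 5 needed")
    coeff = np.polyfit(front.times[m], front.radii[m], 1)
    return float(coeff[0])
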
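"""Diffusion Green's-function kernels and concentration quadratures.

The concentration field created by cells in n dimensions emitting into an
m-dimensional diffusive environment is assembled from ring/shell kernels
G_{n,m}(r, t; R, T): ``a rho dT dR G`` is the concentration observed at
radius r and time t due to the shell of cells at radius R emitting during
dT at time T.  All kernels derive from the free-space heat kernel

    P_m(x, tau) = (4 pi D tau)^(-m/2) exp(-x^2 / 4 D tau)

by integrating over the source shell, mirroring n=1 sources about the
origin, applying a single image factor of 2 when m > n (semi-infinite
environment) and dividing by h (film) or h^2 (channel) for confined
directions.  For cells in 2D the angular integral produces the modified
Bessel function I0, which is always evaluated in exponentially scaled form
to avoid overflow.

The R-integral of each kernel over a band [0, b] has a closed form:
error functions for cells in 1D and 3D, and the Rician CDF (Marcum Q) for
cells in 2D.  Concentrations therefore reduce to one-dimensional time
quadratures, performed internally in natural units (length D/v, time
D/v^2, concentration Cth) in which the activation threshold is exactly 1.

First-order decay of the molecule is not included in these kernels; it
would amount to an extra factor exp(-gamma tau) in every propagator (decay
is available numerically in the PDE module).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import special, stats

from .params import Geometry, PhysicalParams

if TYPE_CHECKING:  # pragma: no cover
    from .front import FrontTrajectory

SQRT_PI = np.sqrt(np.pi)

__all__ = [
    "point_propagator", "ring_kernel", "concentration_from_colony",
    "concentration_from_front", "steady_state_colony", "QuadratureOptions",
]


# ---------------------------------------------------------------------------
# dimensional kernels
# ---------------------------------------------------------------------------

def point_propagator(m: int, distance, tau, D: float):
    """Free-space heat kernel in m dimensions, (4 pi D tau)^(-m/2) e^(-x^2/4Dtau)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    x = np.asarray(distance, dtype=float)
    return (4 * np.pi * D * tau) ** (-m / 2) * np.exp(-x * x / (4 * D * tau))


def ring_kernel(geom: Geometry, r, R, tau, D: float, h: float | None = None):
    """G_{n,m}(r, t; R, T) with tau = t - T, per unit source radius R.

    The shell measure is 2 (mirror pair) for n=1, 2 pi R for n=2 and
    4 pi R^2 for n=3; a factor 2 is included when m > n; thin films and
    channels divide by h or h^2.  Cells-in-2D kernels use the scaled Bessel
    function I0e combined with exp(-(r-R)^2/4Dtau) so they never overflow.
    """
    pair = geom.pair
    r = np.asarray(r, dtype=float)
    R = np.asarray(R, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    if pair in ((1, 1), (1, 2), (2, 2)) and h is None:
        raise ValueError(f"geometry {pair} requires h")
    if pair == (1, 1):
        return (point_propagator(1, r - R, tau, D)
                + point_propagator(1, r + R, tau, D)) / h ** 2
    if pair == (1, 2):
        return 2 * (point_propagator(2, r - R, tau, D)
                    + point_propagator(2, r + R, tau, D)) / h
    if pair in ((2, 2), (2, 3)):
        sigma2 = 2 * D * tau
        gauss = np.exp(-(r - R) ** 2 / (2 * sigma2))
        bess = special.ive(0, r * R / sigma2)
        if pair == (2, 2):
            return 2 * np.pi * R / (4 * np.pi * D * tau) * gauss * bess / h
        return (2 * 2 * np.pi * R * (4 * np.pi * D * tau) ** -1.5
                * gauss * bess)
    if pair == (3, 3):
        l2 = 4 * D * tau
        pref = (4 * np.pi * D * tau) ** -0.5
        with np.errstate(divide="ignore", invalid="ignore"):
            val = (R / r) * pref * (np.exp(-(r - R) ** 2 / l2)
                                    - np.exp(-(r + R) ** 2 / l2))
        # r -> 0 limit: 4 pi R^2 * P_3(R, tau)
        small = np.broadcast_to(r, val.shape) < 1e-12 * np.sqrt(l2)
        if np.any(small):
            lim = 4 * np.pi * R ** 2 * point_propagator(3, R, tau, D)
            val = np.where(small, np.broadcast_to(lim, val.shape), val)
        return val
    raise ValueError(f"unsupported geometry {pair}")  # pragma: no cover


# ---------------------------------------------------------------------------
# nondimensional core (length D/v, time D/v^2, concentration Cth)
# ---------------------------------------------------------------------------

def _rice_cdf(b, nu, sigma2):
    """P(X <= b) for a Rician X with location nu and scale sqrt(sigma2).

    Equals the R-integral of the normalized cells-in-2D ring kernel;
    1 - Q1(nu/sigma, b/sigma) = ncx2.cdf(b^2/sigma2, 2, nu^2/sigma2).
    A Gaussian approximation (mean nu + sigma^2/2nu) replaces the Boost
    evaluation above SNR^2 = 1e4, where it is accurate to < 1e-6.
    """
    b, nu, sigma2 = np.broadcast_arrays(
        np.asarray(b, float), np.asarray(nu, float), np.asarray(sigma2, float))
    snr2 = nu * nu / sigma2
    out = np.empty(b.shape)
    big = snr2 > 1e4
    if np.any(~big):
        out[~big] = stats.ncx2.cdf(
            (b * b / sigma2)[~big], 2, snr2[~big])
    if np.any(big):
        mu = nu + sigma2 / (2 * nu)
        out[big] = special.ndtr(((b - mu) / np.sqrt(sigma2))[big])
    return out


def _band_33(b, r, tau):
    """R-integral over [0, b] of the spherical-shell kernel (natural units).

    The closed antiderivative subtracts terms of order 4*tau to produce an
    O(1) result, so for tau >> (r+b)^2 it loses all precision; there the
    expansion of the shell kernel around the point-source limit is used
    instead (relative truncation error < ~1e-6 at the switch).
    """
    b, r, tau = np.broadcast_arrays(np.asarray(b, float),
                                    np.asarray(r, float),
                                    np.asarray(tau, float))
    l = np.sqrt(4 * tau)
    out = np.empty(b.shape)
    big = tau > 25.0 * (r + b) ** 2
    small = ~big
    if np.any(small):
        bs, rs, ls, ts = b[small], r[small], l[small], tau[small]

        def anti_minus(R):
            return (-(ls * ls / 2) * np.exp(-((R - rs) / ls) ** 2)
                    + rs * ls * SQRT_PI / 2 * special.erf((R - rs) / ls))

        def anti_plus(R):
            return (-(ls * ls / 2) * np.exp(-((R + rs) / ls) ** 2)
                    - rs * ls * SQRT_PI / 2 * special.erf((R + rs) / ls))

        pref = 1.0 / (rs * np.sqrt(4 * np.pi * ts))
        out[small] = pref * (anti_minus(bs) - anti_minus(0.0)
                             - anti_plus(bs) + anti_plus(0.0))
    if np.any(big):
        bb, rb, tb = b[big], r[big], tau[big]
        # 4 pi (4 pi tau)^(-3/2) e^(-r^2/4tau) int_0^b R^2 e^(-R^2/4tau)
        #   * sinh(rR/2tau)/(rR/2tau) dR, expanded to second order
        series = (bb ** 3 / 3 - bb ** 5 / (20 * tb)
                  + bb ** 7 / (224 * tb ** 2)
                  + rb ** 2 * bb ** 5 / (120 * tb ** 2))
        out[big] = (4 * np.pi * (4 * np.pi * tb) ** -1.5
                    * np.exp(-rb * rb / (4 * tb)) * series)
    return out


def source_band(pair: tuple[int, int], r, b, tau):
    """Nondimensional concentration rate at radius r from the band R in [0,b].

    c_hat(r, t) = int_0^t source_band(pair, r, b(T), t - T) dT, with the
    relay threshold at c_hat = 1.  Vectorized over tau/b/r.
    """
    tau = np.asarray(tau, float)
    l = np.sqrt(4 * tau)
    if pair == (1, 1):
        return 0.5 * (special.erf((r + b) / l) - special.erf((r - b) / l))
    if pair == (2, 2):
        return _rice_cdf(b, r, 2 * tau)
    if pair == (1, 2):
        return (np.pi / 2) / np.sqrt(4 * np.pi * tau) * (
            special.erf((r + b) / l) - special.erf((r - b) / l))
    if pair == (2, 3):
        return np.pi / np.sqrt(4 * np.pi * tau) * _rice_cdf(b, r, 2 * tau)
    if pair == (3, 3):
        return _band_33(b, r, tau)
    raise ValueError(f"unsupported geometry {pair}")  # pragma: no cover


@dataclass(frozen=True)
class QuadratureOptions:
    """Tolerances and panelization of the history quadratures.

    ``atol`` is absolute, in units of Cth.  The history time-integral uses
    per-segment Gauss-Legendre after the substitution u = sqrt(t - T) (which
    removes the half-space kernels' endpoint singularity exactly); segments
    older than ``recent_segments`` steps are merged into geometrically
    growing panels (ratio ``coarsen``), and the pre-initiation colony era is
    covered by ``init_panels`` panels.
    """

    atol: float = 1e-4
    gauss_order: int = 6
    recent_segments: int = 64
    coarsen: float = 1.25
    init_panels: int = 16


DEFAULT_QUAD = QuadratureOptions()


def _colony_u_edges(t: float) -> np.ndarray:
    """Panel edges in u = sqrt(tau) for the colony time quadrature.

    Geometric refinement toward u = 0 resolves the turn-on of the band
    integral at small tau; beyond u = 1 geometric growth (ratio 1.15)
    keeps the panel count logarithmic in t, which matters because
    small-colony initiation times can reach astronomical multiples of
    D/v^2.
    """
    s = np.sqrt(t)
    parts = [np.array([0.0]), np.geomspace(min(1e-3, s / 8), min(1.0, s), 16)]
    if s > 1.0:
        n = max(2, int(np.ceil(np.log(s) / np.log(1.15))))
        parts.append(np.geomspace(1.0, s, n))
    parts.append(np.array([s]))
    return np.unique(np.concatenate(parts))


def colony_concentration_nd(pair, r, t, ri, opts: QuadratureOptions = DEFAULT_QUAD):
    """c_hat(r, t) for a constantly emitting colony of radius ri (natural units)."""
    if t <= 0:
        return 0.0
    x, w = _gauss_panels(_colony_u_edges(t), opts.gauss_order)
    return float(np.sum(w * 2 * x * source_band(pair, r, ri, x * x)))


def steady_state_nd(pair, r, ri, opts: QuadratureOptions = DEFAULT_QUAD):
    """t -> infinity limit of colony_concentration_nd; m=3 environments only.

    1D/2D environments have no steady state (the concentration diverges
    logarithmically or faster), so requesting one is an error.
    """
    if pair not in ((2, 3), (3, 3)):
        raise ValueError("steady state exists only for 3D diffusive environments")
    t0 = (r + ri) ** 2 + 1.0
    x, w = _gauss_panels(_colony_u_edges(t0), opts.gauss_order)
    head = float(np.sum(w * 2 * x * source_band(pair, r, ri, x * x)))
    # tail: substitute tau = 1/w^2; the band integral decays like
    # tau^(-3/2), so the transformed integrand 2 F(1/w^2)/w^3 is smooth
    # and finite at w = 0
    w_edges = np.linspace(0.0, 1.0 / np.sqrt(t0), 25)
    xw, ww = _gauss_panels(w_edges, opts.gauss_order)
    tail = float(np.sum(ww * 2 * source_band(pair, r, ri, 1.0 / xw ** 2)
                        / xw ** 3))
    return head + tail


def _refine_edges(edges: np.ndarray, max_width: float) -> np.ndarray:
    """Subdivide panels wider than max_width (keeps existing edges)."""
    widths = np.diff(edges)
    if not np.any(widths > max_width):
        return edges
    out = [edges[:1]]
    for a, b, w in zip(edges[:-1], edges[1:], widths):
        k = int(np.ceil(w / max_width))
        out.append(np.linspace(a, b, k + 1)[1:])
    return np.concatenate(out)


def _gauss_panels(edges, order):
    """Gauss-Legendre nodes and weights on consecutive panels given by edges."""
    gx, gw = np.polynomial.legendre.leggauss(order)
    a, b = edges[:-1], edges[1:]
    mid = 0.5 * (a + b)[:, None]
    half = 0.5 * (b - a)[:, None]
    x = (mid + half * gx[None, :]).ravel()
    w = (half * gw[None, :]).ravel()
    return x, w


def front_concentration_nd(pair, r, t, times, radii, ri,
                           opts: QuadratureOptions = DEFAULT_QUAD):
    """c_hat(r, t) from an emission region bounded by max(ri, r_c(T)).

    ``times``/``radii`` give the activation front r_c on a grid starting at
    the initiation time; r_c is linearly interpolated between grid points.
    Sources before initiation are the colony alone.  The observer radius r
    is arbitrary (it need not lie on the front), so the same routine serves
    the self-consistent front solver and the gradient computation.
    """
    if t <= times[0]:
        return colony_concentration_nd(pair, r, t, ri, opts)
    if t > times[-1] + 1e-9 * max(times[-1], 1.0):
        raise ValueError("front trajectory does not cover [0, t)")
    # u = sqrt(t - T); recent history resolved per segment, older history
    # merged into geometrically coarsened panels (r_c still interpolated
    # at the quadrature nodes, so coarsening only affects Gauss accuracy).
    useg = np.sqrt(np.maximum(t - times[::-1], 0.0))
    useg = useg[useg <= np.sqrt(t - times[0])]
    n_exact = min(opts.recent_segments + 1, len(useg))
    edges = [useg[:n_exact]]
    rest = useg[n_exact - 1:]
    if len(rest) > 1:
        picked = [rest[0]]
        k, step = 0, 1.0
        while k < len(rest) - 1:
            step *= opts.coarsen
            k = min(k + max(1, int(step)), len(rest) - 1)
            picked.append(rest[k])
        edges.append(np.asarray(picked[1:]))
    u_edges = _refine_edges(np.unique(np.concatenate(edges)), 1.0)
    x_h, w_h = _gauss_panels(u_edges, opts.gauss_order)
    b_h = np.maximum(np.interp(t - x_h * x_h, times, radii), ri)
    # colony era T in [0, t_init]  ->  u in [sqrt(t - t_init), sqrt(t)]
    u_pre = _refine_edges(
        np.sqrt(np.linspace(t - times[0], t, opts.init_panels + 1)), 1.0)
    x_p, w_p = _gauss_panels(u_pre, opts.gauss_order)
    x = np.concatenate([x_h, x_p])
    w = np.concatenate([w_h, w_p])
    b = np.concatenate([b_h, np.full_like(x_p, ri)])
    vals = 2 * x * source_band(pair, r, b, x * x)
    return float(np.sum(w * vals))


# ---------------------------------------------------------------------------
# dimensional API
# ---------------------------------------------------------------------------

def _scales(params: PhysicalParams, geom: Geometry) -> tuple[float, float]:
    from . import asymptotics
    v = asymptotics.wave_speed(params, geom)
    return params.D / v, params.D / v ** 2


def concentration_from_colony(r, t, ri: float, params: PhysicalParams,
                              geom: Geometry,
                              opts: QuadratureOptions = DEFAULT_QUAD):
    """Concentration (molecules/m^3) at radius r, time t from a colony of
    radius ri whose cells emit continuously at rate a from t = 0.

    Vectorized over r and t (broadcast together).
    """
    L, T = _scales(params, geom)
    r_nd, t_nd = np.broadcast_arrays(np.asarray(r, float) / L,
                                     np.asarray(t, float) / T)
    out = np.empty(r_nd.shape)
    for idx in np.ndindex(r_nd.shape):
        out[idx] = colony_concentration_nd(geom.pair, float(r_nd[idx]),
                                           float(t_nd[idx]), ri / L, opts)
    return params.Cth * (out if out.shape else float(out))


def steady_state_colony(r, ri: float, params: PhysicalParams, geom: Geometry,
                        opts: QuadratureOptions = DEFAULT_QUAD):
    """Steady-state colony concentration (3D diffusive environments only)."""
    L, _ = _scales(params, geom)
    r_nd = np.asarray(r, float) / L
    out = np.empty(r_nd.shape)
    for idx in np.ndindex(r_nd.shape):
        out[idx] = steady_state_nd(geom.pair, float(r_nd[idx]), ri / L, opts)
    return params.Cth * (out if out.shape else float(out))


def concentration_from_front(r, t: float, front: "FrontTrajectory",
                             ri: float, params: PhysicalParams,
                             geom: Geometry,
                             opts: QuadratureOptions = DEFAULT_QUAD):
    """Concentration at (r, t) given the activation-front history r_c(T).

    Every radius below max(ri, r_c(T)) emits at time T; this is the relay
    self-consistency integrand, evaluated at an arbitrary observer radius.
    """
    L, T = _scales(params, geom)
    times_nd = np.asarray(front.times, float) / T
    radii_nd = np.asarray(front.radii, float) / L
    r_nd = np.asarray(r, float) / L
    out = np.empty(r_nd.shape)
    for idx in np.ndindex(r_nd.shape):
        out[idx] = front_concentration_nd(
            geom.pair, float(r_nd[idx]), t / T, times_nd, radii_nd,
            ri / L, opts)
    return params.Cth * (out if out.shape else float(out))
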
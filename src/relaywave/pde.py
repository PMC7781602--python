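"""Direct numerical integration of the relay reaction–diffusion equation.

This module is the independent oracle for the Green's-function machinery:
it integrates

    dc/dt = D Lap(c) + (a rho / h^k) f(c)      (thin film / channel)
    dc/dt = D Lap(c) + a rho delta(z) f(c)     (cells under a half-space)

with Heaviside or Hill activation on conservative finite-volume grids.
Matched-dimension (thin) systems reduce to a single radial coordinate;
mismatched systems are solved on the (r, z >= 0) half-space with the
singular cell layer converted exactly into a flux boundary condition
-D dc/dz|_{z=0} = a rho f(c(r, 0, t)) — the delta function is never
discretized.  Diffusion (and optional first-order decay gamma) is treated
implicitly (Crank–Nicolson, sparse LU factorized once); the bounded source
is explicit with one corrector pass, so there is no CFL restriction.

Everything is computed in natural units internally (length D/v, time
D/v^2, concentration Cth, with v the Heaviside asymptotic speed for the
given parameters) and converted at the API boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .front import FrontTrajectory
from .params import Activation, Geometry, PhysicalParams

__all__ = ["GridSpec", "FieldSnapshot", "SimResult", "simulate_thin",
           "simulate_thick", "measure_wave_speed"]


@dataclass(frozen=True)
class GridSpec:
    """Grid resolution in natural units (D/v and D/v^2).

    Defaults resolve the front boundary layer with 20 cells (dr = D/20v)
    and step at dt = D/20 v^2.  ``rmax`` defaults to 1.3 t_end + ri + 12
    (natural units) so the front never feels the outer boundary; ``zmax``
    defaults to 6 sqrt(t_end), i.e. six diffusion lengths.  The z grid is
    geometrically stretched away from the cell layer (first spacing
    ``dz0``, ratio ``zratio``).
    """

    dr: float = 0.05
    dt: float = 0.05
    rmax: Optional[float] = None
    dz0: float = 0.05
    zratio: float = 1.08
    zmax: Optional[float] = None


@dataclass(frozen=True)
class FieldSnapshot:
    """Concentration profile at one time (SI units).

    For thick media ``c`` has shape (nr, nz) and ``z_grid`` holds the
    cell-center heights; the cell-plane profile is ``surface``.
    """

    t: float
    r_grid: np.ndarray
    c: np.ndarray
    z_grid: Optional[np.ndarray] = None
    surface: Optional[np.ndarray] = None

    @property
    def plane(self) -> np.ndarray:
        """Concentration at the cell layer."""
        if self.surface is not None:
            return self.surface
        return self.c


@dataclass(frozen=True)
class SimResult:
    snapshots: list[FieldSnapshot]
    front: FrontTrajectory
    params: PhysicalParams
    geometry: Geometry
    activation: Activation
    grid: GridSpec
    #: per-step bookkeeping in consistent (shared) units: domain-integrated
    #: concentration and the cumulative source integral; equal when gamma = 0
    times: np.ndarray = field(default_factory=lambda: np.empty(0))
    mass: np.ndarray = field(default_factory=lambda: np.empty(0))
    emitted: np.ndarray = field(default_factory=lambda: np.empty(0))


def _radial_operator(nr: int, dr: float, ndim: int):
    """Conservative finite-volume Laplacian on cell centers (j+1/2) dr with
    no-flux boundaries; returns (L, centers, volumes)."""
    j = np.arange(nr)
    rc = (j + 0.5) * dr
    faces = np.arange(nr + 1) * dr
    if ndim == 1:
        area = np.ones(nr + 1)
        vol = np.full(nr, dr)
    elif ndim == 2:
        area = faces
        vol = rc * dr
    else:
        area = faces ** 2
        vol = rc ** 2 * dr
    lo = area[1:-1] / (dr * vol[1:])
    hi = area[1:-1] / (dr * vol[:-1])
    main = np.zeros(nr)
    main[1:] -= lo
    main[:-1] -= hi
    return sp.diags([lo, main, hi], [-1, 0, 1], format="csr"), rc, vol


def _z_grid(dz0: float, zmax: float, ratio: float) -> np.ndarray:
    zs = [0.0, dz0]
    d = dz0
    while zs[-1] < zmax:
        d *= ratio
        zs.append(zs[-1] + d)
    return np.asarray(zs)


def _level_set(rc: np.ndarray, c: np.ndarray, th: float = 1.0) -> float:
    """Outermost radius where c crosses th (linear interpolation); 0 if none."""
    above = c >= th
    if not above.any():
        return 0.0
    idx = int(np.where(above)[0][-1])
    if idx == len(rc) - 1:
        return float(rc[-1])
    c0, c1 = c[idx], c[idx + 1]
    return float(rc[idx] + (th - c0) / (c1 - c0) * (rc[idx + 1] - rc[idx]))


def _scales(params: PhysicalParams, geom: Geometry):
    from . import asymptotics
    v = asymptotics.wave_speed(params, geom)
    return v, params.D / v, params.D / v ** 2


def simulate_thin(params: PhysicalParams, activation: Activation, ri: float,
                  t_end: float, geom: Optional[Geometry] = None,
                  grid: Optional[GridSpec] = None, relay: bool = True,
                  snapshot_times: Optional[list[float]] = None) -> SimResult:
    """Integrate the thin-medium (matched-dimension) relay equation.

    ``geom`` defaults to cells in 2D / diffusion in 2D.  The colony r < ri
    emits from t = 0 regardless of threshold; with ``relay=False`` only the
    colony ever emits (simple-diffusion oracle mode used to cross-check the
    Green's-function quadratures).
    """
    geom = geom or Geometry(2, 2)
    if not geom.matched:
        raise ValueError("simulate_thin requires matched dimensions")
    grid = grid or GridSpec()
    v, L, T = _scales(params, geom)
    t_end_nd = t_end / T
    ri_nd = ri / L
    gamma_nd = params.gamma * T
    rmax = grid.rmax or (1.3 * t_end_nd + ri_nd + 12)
    nr = int(np.ceil(rmax / grid.dr))
    Lap, rc, vol = _radial_operator(nr, grid.dr, geom.cell_dim)
    dt = grid.dt
    I = sp.identity(nr, format="csr")
    solve = spla.factorized((I - dt / 2 * (Lap - gamma_nd * I)).tocsc())
    B = (I + dt / 2 * (Lap - gamma_nd * I)).tocsr()

    colony = rc < ri_nd

    def act(c: np.ndarray) -> np.ndarray:
        f = activation(c)
        if relay:
            return np.where(colony, 1.0, f)
        return np.where(colony, 1.0, 0.0)

    nsteps = int(round(t_end_nd / dt))
    times_nd = np.arange(nsteps + 1) * dt
    fronts = np.zeros(nsteps + 1)
    mass = np.zeros(nsteps + 1)
    emitted = np.zeros(nsteps + 1)
    c = np.zeros(nr)
    snaps: list[FieldSnapshot] = []
    snap_nd = sorted(t / T for t in (snapshot_times or []))
    geo_factor = {1: 2.0, 2: 2 * np.pi, 3: 4 * np.pi}[geom.cell_dim]

    def take_snap(t_nd: float, c_nd: np.ndarray) -> None:
        snaps.append(FieldSnapshot(t=t_nd * T, r_grid=rc * L,
                                   c=c_nd * params.Cth))

    for k in range(1, nsteps + 1):
        s = act(c)
        c_pred = solve(B @ c + dt * s)
        s_mid = 0.5 * (s + act(c_pred))   # one corrector pass on the source
        c = solve(B @ c + dt * s_mid)
        fronts[k] = _level_set(rc, c)
        mass[k] = geo_factor * np.sum(c * vol)
        emitted[k] = emitted[k - 1] + geo_factor * dt * np.sum(s_mid * vol)
        while snap_nd and times_nd[k] >= snap_nd[0] - 1e-9:
            take_snap(times_nd[k], c)
            snap_nd.pop(0)
    if not snaps or snaps[-1].t < t_end - 1e-9:
        take_snap(times_nd[-1], c)

    front = FrontTrajectory(times=times_nd * T, radii=fronts * L, ri=ri,
                            dt=dt * T, model="relay" if relay else
                            "simple_diffusion", geometry=geom)
    # bookkeeping in SI units: mass is in units of Cth * (D/v)^n; emission
    # should equal a * (active measure) * t -- report both consistently
    unit = params.Cth * L ** geom.cell_dim
    return SimResult(snapshots=snaps, front=front, params=params,
                     geometry=geom, activation=activation, grid=grid,
                     times=times_nd * T, mass=mass * unit,
                     emitted=emitted * unit)


def simulate_thick(params: PhysicalParams, activation: Activation, ri: float,
                   t_end: float, geom: Optional[Geometry] = None,
                   grid: Optional[GridSpec] = None, relay: bool = True,
                   snapshot_times: Optional[list[float]] = None) -> SimResult:
    """Integrate the mismatched-dimension relay on the (r, z>=0) half-space.

    Supports cells in 2D under 3D diffusion (axisymmetric r) and cells in
    1D under half-plane 2D diffusion (Cartesian r >= 0 with mirror
    symmetry).  The cell layer enters as the flux condition
    -D dc/dz = a rho f(c_surf) at z = 0; activation is decided on the
    reconstructed surface concentration c_surf = c_center +
    (flux/D) dz0/2, ties counting as active.
    """
    geom = geom or Geometry(2, 3)
    if geom.matched:
        raise ValueError("simulate_thick requires mismatched dimensions")
    grid = grid or GridSpec()
    v, L, T = _scales(params, geom)
    t_end_nd = t_end / T
    ri_nd = ri / L
    gamma_nd = params.gamma * T
    rmax = grid.rmax or (1.3 * t_end_nd + ri_nd + 12)
    nr = int(np.ceil(rmax / grid.dr))
    in_plane_dim = geom.cell_dim   # 1 -> Cartesian, 2 -> cylindrical
    Lr, rc, vol_r = _radial_operator(nr, grid.dr, in_plane_dim)
    zmax = grid.zmax or (6 * np.sqrt(t_end_nd) + 1)
    zf = _z_grid(grid.dz0, zmax, grid.zratio)
    nz = len(zf) - 1
    zc = 0.5 * (zf[1:] + zf[:-1])
    dzc = np.diff(zf)
    dz_if = np.diff(zc)
    lo = 1.0 / (dz_if * dzc[1:])
    hi = 1.0 / (dz_if * dzc[:-1])
    main = np.zeros(nz)
    main[1:] -= lo
    main[:-1] -= hi
    Lz = sp.diags([lo, main, hi], [-1, 0, 1])
    Lap = sp.kron(Lr, sp.identity(nz)) + sp.kron(sp.identity(nr), Lz)
    N = nr * nz
    dt = grid.dt
    I = sp.identity(N, format="csr")
    solve = spla.factorized((I - dt / 2 * (Lap - gamma_nd * I)).tocsc())
    B = (I + dt / 2 * (Lap - gamma_nd * I)).tocsr()

    colony = rc < ri_nd
    # nondim surface flux strength: -dc/dz|_0 = (pi/2) f for both supported
    # pairs (the factor collapses to pi/2 once lengths are in D/v and the
    # speed law v = 2 a rho / (pi h^k Cth) is substituted)
    flux = np.pi / 2
    pref = flux / dzc[0]
    half = dzc[0] / 2

    def surface_and_act(c_cen: np.ndarray, a_guess: np.ndarray):
        """Self-consistent surface concentration and activation."""
        if activation.kind == "heaviside":
            a = activation(c_cen + flux * half)   # active iff active is stable
            a = np.where(colony, 1.0, a if relay else 0.0)
            return c_cen + flux * a * half, a
        a = a_guess
        for _ in range(6):
            cs = c_cen + flux * a * half
            a = activation(cs)
            a = np.where(colony, 1.0, a if relay else 0.0)
        return c_cen + flux * a * half, a

    nsteps = int(round(t_end_nd / dt))
    times_nd = np.arange(nsteps + 1) * dt
    fronts = np.zeros(nsteps + 1)
    mass = np.zeros(nsteps + 1)
    emitted = np.zeros(nsteps + 1)
    c = np.zeros((nr, nz))
    snaps: list[FieldSnapshot] = []
    snap_nd = sorted(t / T for t in (snapshot_times or []))
    geo_factor = 2.0 if in_plane_dim == 1 else 2 * np.pi

    def take_snap(t_nd, c_nd, csurf):
        snaps.append(FieldSnapshot(
            t=t_nd * T, r_grid=rc * L, c=c_nd * params.Cth, z_grid=zc * L,
            surface=csurf * params.Cth))

    a_prev = np.where(colony, 1.0, 0.0)
    for k in range(1, nsteps + 1):
        _, a = surface_and_act(c[:, 0], a_prev)
        S = np.zeros((nr, nz))
        S[:, 0] = pref * a
        c1 = solve(B @ c.ravel() + dt * S.ravel()).reshape(nr, nz)
        _, a1 = surface_and_act(c1[:, 0], a)
        S[:, 0] = pref * 0.5 * (a + a1)
        c = solve(B @ c.ravel() + dt * S.ravel()).reshape(nr, nz)
        csurf, a_prev = surface_and_act(c[:, 0], a1)
        fronts[k] = _level_set(rc, csurf)
        mass[k] = geo_factor * np.sum((c * dzc[None, :]) * vol_r[:, None])
        emitted[k] = emitted[k - 1] + geo_factor * dt * np.sum(
            S[:, 0] * dzc[0] * vol_r)
        while snap_nd and times_nd[k] >= snap_nd[0] - 1e-9:
            take_snap(times_nd[k], c, csurf)
            snap_nd.pop(0)
    if not snaps or snaps[-1].t < t_end - 1e-9:
        csurf, _ = surface_and_act(c[:, 0], a_prev)
        take_snap(times_nd[-1], c, csurf)

    front = FrontTrajectory(times=times_nd * T, radii=fronts * L, ri=ri,
                            dt=dt * T, model="relay" if relay else
                            "simple_diffusion", geometry=geom)
    unit = params.Cth * L ** geom.diff_dim
    return SimResult(snapshots=snaps, front=front, params=params,
                     geometry=geom, activation=activation, grid=grid,
                     times=times_nd * T, mass=mass * unit,
                     emitted=emitted * unit)


def measure_wave_speed(sim: SimResult, t_measure: float) -> float:
    """Slope of the threshold level-set radius over the last 20% of
    [0, t_measure] (m/s)."""
    fr = sim.front
    m = (fr.times >= 0.8 * t_measure) & (fr.times <= t_measure)
    m &= fr.radii > fr.ri   # front must have detached from the colony
    if m.sum() < 5:
        raise ValueError("front not resolved over the measurement window")
    return float(np.polyfit(fr.times[m], fr.radii[m], 1)[0])
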
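"""Neutrophil-swarming information fronts: prediction, fitting, gradients.

In swarming assays, neutrophils settle uniformly on a glass slide (cells
in 2D) under a millimetres-thick medium (diffusion in a semi-infinite 3D
half-space) with a chemoattractant-coated target of radius ri at the
origin.  Tracking the cells yields a chemotactic-index map <cos theta>(r, t)
whose sharp boundary — the information front — separates cells already
chemotaxing toward the target from undirected ones.  This module predicts
that front under the relay model (target cells emit from t = 0, recruited
cells join above threshold), fits the two free parameters Cth/(a rho) and
D to observed front points, constructs the matched simple-diffusion
comparison model, and compares the radial concentration gradients the two
models offer a chemotaxing cell.

The inward migration of the cells themselves (u ~ 0.3 µm/s << v) is
ignored throughout, as it has a negligible effect on front propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from . import front as front_mod
from . import greens
from .front import FrontTrajectory
from .greens import DEFAULT_QUAD, QuadratureOptions
from .params import Geometry, PhysicalParams

GEOM = Geometry(2, 3)

#: measured neutrophil crawling speed (m/s); documented, deliberately unused
NEUTROPHIL_SPEED_U = 0.3e-6


def _params_from(cth_over_arho: float, D: float) -> PhysicalParams:
    """Thick-medium model has exactly two parameters; pick a=rho=1."""
    return PhysicalParams(D=D, a=1.0, rho=1.0, Cth=cth_over_arho)


@dataclass(frozen=True)
class FrontObservations:
    """Observed information-front samples (t_i, r_i), optionally weighted."""

    times: np.ndarray           # s, strictly positive
    radii: np.ndarray           # m, >= target radius
    weights: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "radii", np.asarray(self.radii, float))
        if self.times.size != self.radii.size:
            raise ValueError("times and radii must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("observation times must be positive")


@dataclass(frozen=True)
class ChemotacticIndexMap:
    """<cos theta> binned in radius and time; ~1 directed, ~0 undirected."""

    r_bins: np.ndarray          # bin centers, m
    t_bins: np.ndarray          # bin centers, s
    values: np.ndarray          # shape (len(t_bins), len(r_bins)), in [-1, 1]


@dataclass(frozen=True)
class SwarmFit:
    """Fitted relay parameters and the wave speed they imply."""

    cth_over_arho: float        # s/m
    D: float                    # m^2/s
    residual: float             # sqrt(mean squared radial residual), m
    model: str = "relay"

    @property
    def implied_v(self) -> float:
        """v = 2 a rho / (pi Cth) for the thick-medium relay."""
        return 2.0 / (np.pi * self.cth_over_arho)


MAX_NATURAL_DURATION = 100.0


def predict_front(cth_over_arho: float, D: float, ri: float,
                  t_grid, dt: Optional[float] = None,
                  model: str = "relay",
                  opts: QuadratureOptions = DEFAULT_QUAD) -> FrontTrajectory:
    """Information front for a permanently emitting target of radius ri.

    ``t_grid`` may be a scalar end time or an array (its max is used; the
    trajectory's own uniform grid is returned).  ``model`` selects the
    relay or the simple-diffusion (target-only) front.  Parameter
    combinations for which the requested horizon exceeds
    ``MAX_NATURAL_DURATION`` units of D/v^2 are rejected (the front would
    need thousands of steps; such parameters are far outside the regime the
    swarming data constrains, and the fit treats them as inadmissible).
    """
    params = _params_from(cth_over_arho, D)
    t_end = float(np.max(t_grid))
    v = 2.0 / (np.pi * cth_over_arho)
    if model == "relay" and t_end * v * v / D > MAX_NATURAL_DURATION:
        raise RuntimeError(
            f"horizon {t_end} s exceeds {MAX_NATURAL_DURATION} D/v^2 at "
            f"these parameters")
    if model == "relay":
        return front_mod.propagate_front(params, GEOM, ri, t_end, dt=dt,
                                         opts=opts)
    return front_mod.simple_diffusion_front(params, GEOM, ri, t_end, dt=dt,
                                            opts=opts)


def _model_radii(traj: FrontTrajectory, times: np.ndarray,
                 ri: float) -> np.ndarray:
    """Front radius at observation times; ri before the front exists."""
    if len(traj) == 0:
        return np.full_like(times, ri)
    return np.asarray(traj.radius_at(times), float)


def fit_front(obs: FrontObservations, ri: float,
              initial_guess: tuple[float, float] = (3e5, 1e-10),
              model: str = "relay", dt: Optional[float] = None,
              opts: QuadratureOptions = DEFAULT_QUAD) -> SwarmFit:
    """Weighted least squares for (Cth/a rho, D) against observed front points.

    Minimizes radial residuals between the predicted and observed front
    over the two thick-medium model parameters (in log space, since both
    are positive scale parameters).  Needs at least 4 points spanning early
    and late times to constrain both the initial diffusive transient and
    the asymptotic slope.
    """
    if obs.times.size < 4:
        raise ValueError("need at least 4 observation points")
    w = np.ones_like(obs.times) if obs.weights is None else obs.weights
    sw = np.sqrt(w / w.sum())

    def residuals(logp):
        q, D = np.exp(logp)
        try:
            traj = predict_front(q, D, ri, obs.times.max(), dt=dt,
                                 model=model, opts=opts)
        except RuntimeError:   # does not initiate: push back with a penalty
            return 1e3 * np.ones_like(obs.times)
        return sw * (_model_radii(traj, obs.times, ri) - obs.radii)

    sol = optimize.least_squares(
        residuals, np.log(np.asarray(initial_guess, float)),
        method="lm", xtol=1e-8, ftol=1e-10)
    if not sol.success:
        raise RuntimeError(f"front fit did not converge: {sol.message}")
    q, D = np.exp(sol.x)
    rms = float(np.sqrt(np.mean((sol.fun / sw) ** 2)))
    return SwarmFit(cth_over_arho=float(q), D=float(D), residual=rms,
                    model=model)


def match_simple_diffusion_threshold(relay_fit: SwarmFit, ri: float,
                                     t_match: float,
                                     dt: Optional[float] = None,
                                     opts: QuadratureOptions = DEFAULT_QUAD
                                     ) -> float:
    """Simple-diffusion Cth/(a rho) whose front reaches the relay front's
    radius at t_match (s/m).

    The diffusion front radius at fixed t is monotone decreasing in the
    threshold, so the match is a bracketed root.  Larger t_match gives a
    larger matched threshold: the relay front outruns any diffusive one.
    """
    relay = predict_front(relay_fit.cth_over_arho, relay_fit.D, ri,
                          t_match, dt=dt, opts=opts)
    r_target = float(relay.radius_at(t_match))
    if r_target <= ri * (1 + 1e-9):
        raise ValueError("relay front has not left the target by t_match; "
                         "the match is degenerate")

    def radius_minus_target(log_q: float) -> float:
        q = np.exp(log_q)
        params = _params_from(q, relay_fit.D)
        c = greens.concentration_from_colony(r_target, t_match, ri, params,
                                             GEOM, opts)
        # c(r_target) >= Cth  <=>  diffusion front at/beyond r_target
        return c / params.Cth - 1.0

    lo, hi = np.log(1e2), np.log(relay_fit.cth_over_arho)
    if radius_minus_target(hi) > 0:
        raise RuntimeError("relay threshold itself already reaches the match "
                           "radius; no larger diffusion threshold exists")
    log_q = optimize.brentq(radius_minus_target, lo, hi, xtol=1e-10)
    return float(np.exp(log_q))


@dataclass(frozen=True)
class GradientProfiles:
    """Radial gradients dC/dr at the cell plane for both models."""

    times: np.ndarray               # s
    r: np.ndarray                   # m
    relay: np.ndarray               # (ntimes, nr), molecules/m^3 per m
    diffusion: np.ndarray           # same shape
    relay_front: np.ndarray         # front radii at `times`, m
    diffusion_front: np.ndarray


def gradient_profiles(relay_params: tuple[float, float],
                      diffusion_params: tuple[float, float], ri: float,
                      times, r_grid=None, dt: Optional[float] = None,
                      opts: QuadratureOptions = DEFAULT_QUAD
                      ) -> GradientProfiles:
    """Compare dC/dr of the relay and simple-diffusion models.

    ``relay_params`` / ``diffusion_params`` are (Cth/a rho, D) for each
    model.  Gradients are central differences of the Green's-function
    concentrations on a refined radial grid, at the cell plane.  Since the
    two models carry different (arbitrary) a rho, gradients are reported
    per unit a rho; ratios between models at the same location are the
    meaningful quantity.
    """
    times = np.atleast_1d(np.asarray(times, float))
    q_r, D_r = relay_params
    q_d, D_d = diffusion_params
    p_relay = _params_from(q_r, D_r)
    p_diff = _params_from(q_d, D_d)
    t_end = float(times.max())
    relay_traj = predict_front(q_r, D_r, ri, t_end, dt=dt, opts=opts)
    diff_traj = predict_front(q_d, D_d, ri, t_end, dt=dt,
                              model="simple_diffusion", opts=opts)
    if r_grid is None:
        r_max = 1.5 * float(relay_traj.radii.max())
        r_grid = np.linspace(ri / 4, r_max, 200)
    r_grid = np.asarray(r_grid, float)
    h = np.diff(r_grid).min() / 4
    rel = np.empty((times.size, r_grid.size))
    dif = np.empty((times.size, r_grid.size))
    for i, t in enumerate(times):
        c_hi = greens.concentration_from_front(r_grid + h, t, relay_traj, ri,
                                               p_relay, GEOM, opts)
        c_lo = greens.concentration_from_front(r_grid - h, t, relay_traj, ri,
                                               p_relay, GEOM, opts)
        rel[i] = (c_hi - c_lo) / (2 * h)
        d_hi = greens.concentration_from_colony(r_grid + h, t, ri, p_diff,
                                                GEOM, opts)
        d_lo = greens.concentration_from_colony(r_grid - h, t, ri, p_diff,
                                                GEOM, opts)
        dif[i] = (d_hi - d_lo) / (2 * h)
    relay_front = relay_traj.radius_at(times)
    if len(diff_traj):
        diff_front = diff_traj.radius_at(times)
    else:
        diff_front = np.full_like(times, np.nan)
    return GradientProfiles(times=times, r=r_grid, relay=rel, diffusion=dif,
                            relay_front=np.asarray(relay_front),
                            diffusion_front=np.asarray(diff_front))


def synth_front_map(cth_over_arho: float = 3.66e5, D: float = 1.25e-10,
                    ri: float = 100e-6, noise: float = 0.05,
                    directed_value: float = 0.95,
                    r_max: float = 600e-6, n_r: int = 24,
                    t_max: float = 500.0, n_t: int = 20,
                    seed: int = 0, dt: Optional[float] = None,
                    opts: QuadratureOptions = DEFAULT_QUAD
                    ) -> tuple[ChemotacticIndexMap, FrontObservations]:
    """Synthetic chemotactic-index map and extracted front observations.

    Emulates the swarming data product: <cos theta> is ``directed_value``
    inside the true relay front and 0 outside, plus i.i.d. Gaussian noise
    of standard deviation ``noise`` (absolute, same scale as the index).
    Front points are then extracted per time bin as the outermost crossing
    of directed_value/2 (linear interpolation between radial bins).  The
    defaults mirror the fitted swarming conditions: Cth/(a rho) =
    3.66e5 s/m, D = 1.25e-10 m^2/s, a 100 µm target, 25 µm radial and 25 s
    temporal bins, 5% noise.

    What this generator does NOT emulate: cell-tracking statistics (finite
    cells per bin, correlated errors near the target), target asphericity,
    and the gradual rise of the chemotactic index behind the front.
    """
    rng = np.random.default_rng(seed)
    truth = predict_front(cth_over_arho, D, ri, t_max, dt=dt, opts=opts)
    r_bins = np.linspace(r_max / n_r / 2, r_max - r_max / n_r / 2, n_r)
    t_bins = np.linspace(t_max / n_t / 2, t_max - t_max / n_t / 2, n_t)
    inside = r_bins[None, :] < np.asarray(truth.radius_at(t_bins))[:, None]
    values = directed_value * inside + rng.normal(0.0, noise, inside.shape)
    np.clip(values, -1.0, 1.0, out=values)

    half = directed_value / 2
    ts, rs = [], []
    for i, t in enumerate(t_bins):
        row = values[i]
        above = row >= half
        if not above.any():
            continue
        j = int(np.where(above)[0][-1])
        if j == n_r - 1:
            r_cross = r_bins[-1]
        else:
            r_cross = r_bins[j] + (half - row[j]) / (row[j + 1] - row[j]) * (
                r_bins[j + 1] - r_bins[j])
        ts.append(t)
        rs.append(max(r_cross, ri))
    obs = FrontObservations(times=np.asarray(ts), radii=np.asarray(rs))
    return ChemotacticIndexMap(r_bins=r_bins, t_bins=t_bins, values=values), obs
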
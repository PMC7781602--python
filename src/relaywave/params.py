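"""Physical parameters, system geometry, natural scales and validity checks.

A diffusive signaling relay is specified by the signaling-molecule
diffusivity ``D``, the per-cell emission rate ``a``, the cell density
``rho``, the activation threshold concentration ``Cth`` and, where the
extracellular medium is effectively lower-dimensional, its thickness ``h``.
The dimensionality of the cell distribution (``cell_dim``) and of the
diffusive environment (``diff_dim``) select the wave-speed law; when the two
differ, the diffusive environment is taken to be semi-infinite on one side
of the cell plane/line, which contributes a factor of two to the source
(method of images).

All quantities are SI: metres, seconds, molecules/m^3. Concentrations are
molecule number densities throughout; conversion to molar units is provided
as a helper only.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass, field
from typing import Optional

import yaml

AVOGADRO = 6.02214076e23

#: supported (cell_dim, diff_dim) pairs
SUPPORTED_GEOMETRIES = {(1, 1), (1, 2), (2, 2), (2, 3), (3, 3)}

#: geometries whose diffusive environment is a thin film / narrow channel and
#: therefore require a thickness h
THIN_GEOMETRIES = {(1, 1), (1, 2), (2, 2)}


@dataclass(frozen=True)
class Geometry:
    """Cell dimension n and diffusion dimension m, m >= n.

    For mismatched dimensions (m > n) the environment is semi-infinite on one
    side of the cell plane/line and the kernels carry a single image factor
    of two.  For (1, 1) the channel has cross-section h x h; for (1, 2) and
    (2, 2) the medium is a film of thickness h.
    """

    cell_dim: int
    diff_dim: int

    def __post_init__(self) -> None:
        pair = (self.cell_dim, self.diff_dim)
        if pair not in SUPPORTED_GEOMETRIES:
            raise ValueError(
                f"unsupported geometry {pair}; supported: "
                f"{sorted(SUPPORTED_GEOMETRIES)}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.cell_dim, self.diff_dim)

    @property
    def matched(self) -> bool:
        return self.cell_dim == self.diff_dim

    @property
    def needs_thickness(self) -> bool:
        return self.pair in THIN_GEOMETRIES

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"cells in {self.cell_dim}D, diffusion in {self.diff_dim}D"


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional inputs of the relay model (SI units).

    Parameters
    ----------
    D : diffusivity of the signaling molecule, m^2/s.
    a : maximal per-cell emission rate, molecules/s.
    rho : cell density, 1/m^n for cells in n dimensions.
    Cth : activation threshold concentration, molecules/m^3.
    h : medium thickness / channel width, m. Required for thin geometries.
    gamma : first-order decay rate of the molecule, 1/s (0 = no decay).
    tau : emission pulse duration, s (inf = continuous emission).
    H : cell size (out-of-plane extent), m; used only in validity checks.
    d : mean spacing between neighbouring cells, m; continuum-limit check.
    """

    D: float
    a: float
    rho: float
    Cth: float
    h: Optional[float] = None
    gamma: float = 0.0
    tau: float = math.inf
    H: Optional[float] = None
    d: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("D", "a", "rho", "Cth"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.h is not None and not self.h > 0:
            raise ValueError("h must be > 0 when given")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not self.tau > 0:
            raise ValueError("tau must be > 0 (inf for continuous emission)")

    def require_thickness(self, geom: Geometry) -> float:
        if not geom.needs_thickness:
            raise ValueError(f"geometry {geom.pair} has no thickness scale")
        if self.h is None:
            raise ValueError(
                f"geometry {geom.pair} requires a medium thickness h")
        return self.h

    @property
    def threshold_time(self) -> float:
        """h*Cth/(a*rho) for thin films — only meaningful with h set."""
        if self.h is None:
            raise ValueError("threshold_time requires h")
        return self.h * self.Cth / (self.a * self.rho)

    @property
    def threshold_per_flux(self) -> float:
        """Cth/(a*rho), s/m — the single thick-medium model parameter."""
        return self.Cth / (self.a * self.rho)


@dataclass(frozen=True)
class Activation:
    """Cellular activation function f(c).

    ``heaviside``: all-or-none emission above Cth, f(c) = Theta[c - Cth].
    ``hill``: graded emission f(c) = c^n / (c^n + Cth^n) of order n; the
    Heaviside switch is the n -> infinity limit.
    """

    kind: str = "heaviside"
    hill_order: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("heaviside", "hill"):
            raise ValueError("activation kind must be 'heaviside' or 'hill'")
        if self.kind == "hill" and self.hill_order < 1:
            raise ValueError("hill_order must be >= 1")

    def __call__(self, c_over_cth):
        """f as a function of c/Cth (dimensionless)."""
        import numpy as np
        x = np.asarray(c_over_cth, dtype=float)
        if self.kind == "heaviside":
            return (x >= 1.0).astype(float)
        xp = np.maximum(x, 0.0)
        xn = xp ** self.hill_order
        return xn / (xn + 1.0)


def natural_scales(params: PhysicalParams, geom: Geometry) -> tuple[float, float]:
    """Return the natural length D/v and time D/v^2 of the relay wave.

    v is the asymptotic wave speed for the given geometry, so the length is
    the width of the concentration boundary layer at the front and the time
    is the lag between threshold crossing and full activation of a region.
    """
    from . import asymptotics

    v = asymptotics.wave_speed(params, geom)
    return params.D / v, params.D / v ** 2


@dataclass(frozen=True)
class ValidityCheck:
    name: str
    value: Optional[float]
    comparison: str           # "<<1" or ">>1"
    threshold: float
    passed: Optional[bool]    # None = skipped (missing optional input)
    note: str = ""


@dataclass(frozen=True)
class ValidityReport:
    checks: tuple[ValidityCheck, ...]

    def __getitem__(self, name: str) -> ValidityCheck:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks if c.passed is not None)

    def summary(self) -> str:
        lines = []
        for c in self.checks:
            if c.passed is None:
                lines.append(f"{c.name:>14}: skipped ({c.note})")
            else:
                status = "pass" if c.passed else "FAIL"
                lines.append(
                    f"{c.name:>14}: {c.value:.3g} {c.comparison} "
                    f"[{status}]" + (f" ({c.note})" if c.note else ""))
        return "\n".join(lines)


def validity_report(params: PhysicalParams, geom: Geometry,
                    much_less: float = 0.25,
                    much_greater: float = 4.0) -> ValidityReport:
    """Evaluate the dimensionless criteria behind the continuum relay model.

    continuum      d*v/4D  << 1   cell spacing small vs boundary layer
    thin_medium    h*v/D   << 1 (thin geometries) or >> 1 (semi-infinite)
    cell_thickness H*v/D   << 1   delta-layer description of the cells
    decay          gamma*D/v^2 << 1   molecule outlives the front passage
    pulse          tau*v^2/D   >> 1   emission outlasts the front passage

    The theory states the criteria only as "<<" / ">>"; the numeric cutoffs
    (default 0.25 and 4) are package conventions and are configurable.
    """
    from . import asymptotics
    v = asymptotics.wave_speed(params, geom)
    checks: list[ValidityCheck] = []

    def add(name, value, comparison, note=""):
        if value is None:
            checks.append(ValidityCheck(name, None, comparison,
                                        much_less if comparison == "<<1"
                                        else much_greater, None, note))
            return
        if comparison == "<<1":
            ok = value < much_less
        else:
            ok = value > much_greater
        checks.append(ValidityCheck(name, value, comparison,
                                    much_less if comparison == "<<1"
                                    else much_greater, ok, note))

    add("continuum", None if params.d is None else params.d * v / (4 * params.D),
        "<<1", "requires mean cell spacing d" if params.d is None else "")
    if params.h is None:
        add("thin_medium", None, "<<1", "requires thickness h")
    elif geom.needs_thickness:
        add("thin_medium", params.h * v / params.D, "<<1",
            "thin-film geometry")
    else:
        add("thin_medium", params.h * v / params.D, ">>1",
            "semi-infinite geometry: medium must be thick")
    add("cell_thickness",
        None if params.H is None else params.H * v / params.D, "<<1",
        "requires cell size H" if params.H is None else "")
    add("decay", params.gamma * params.D / v ** 2, "<<1")
    add("pulse",
        math.inf if math.isinf(params.tau) else params.tau * v ** 2 / params.D,
        ">>1", "continuous emission" if math.isinf(params.tau) else "")
    return ValidityReport(tuple(checks))


def molar_concentration(c_molecules_per_m3: float) -> float:
    """Convert molecules/m^3 to mol/L (helper; core logic never uses molar)."""
    return c_molecules_per_m3 / AVOGADRO / 1e3


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Bundle of model inputs loaded from a YAML/JSON config (SI units)."""

    params: PhysicalParams
    geometry: Geometry
    activation: Activation = field(default_factory=Activation)
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        out = {k: v for k, v in dataclasses.asdict(self.params).items()
               if v is not None}
        if math.isinf(out.get("tau", 1.0)):
            out.pop("tau")
        out["cell_dim"] = self.geometry.cell_dim
        out["diff_dim"] = self.geometry.diff_dim
        out["activation"] = {"kind": self.activation.kind}
        if self.activation.kind == "hill":
            out["activation"]["hill_order"] = self.activation.hill_order
        if self.seed is not None:
            out["seed"] = self.seed
        return out


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file.

    Keys mirror the PhysicalParams/Geometry field names; ``activation`` is an
    optional mapping with ``kind`` and ``hill_order``.
    """
    path = pathlib.Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    act = data.pop("activation", None) or {}
    geom = Geometry(int(data.pop("cell_dim")), int(data.pop("diff_dim")))
    seed = data.pop("seed", None)
    params = PhysicalParams(**{k: float(v) for k, v in data.items()})
    return RunConfig(params=params, geometry=geom,
                     activation=Activation(**act), seed=seed)


def save_config(cfg: RunConfig, path) -> None:
    path = pathlib.Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data))
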
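import numpy as np
import pytest

from relaywave import Geometry, PhysicalParams


def params_for(geom: Geometry, v: float = 2e-6, D: float = 1e-10,
               h: float = 1e-4, **extra) -> PhysicalParams:
    """Parameters with a = rho = 1 engineered to give wave speed v."""
    pair = geom.pair
    if pair == (1, 1):
        cth = D / (v ** 2 * h ** 2)
    elif pair == (2, 2):
        cth = D / (v ** 2 * h)
    elif pair == (3, 3):
        cth = D / v ** 2
        h = None
    elif pair == (1, 2):
        cth = 2 / (np.pi * v * h)
    elif pair == (2, 3):
        cth = 2 / (np.pi * v)
        h = None
    else:  # pragma: no cover
        raise ValueError(pair)
    return PhysicalParams(D=D, a=1.0, rho=1.0, Cth=cth, h=h, **extra)


ALL_GEOMS = [Geometry(1, 1), Geometry(1, 2), Geometry(2, 2), Geometry(2, 3),
             Geometry(3, 3)]


@pytest.fixture
def fig1_system():
    """Thin-film benchmark: D=1e-10 m^2/s, h Cth/(a rho)=25 s -> v=2 µm/s."""
    geom = Geometry(2, 2)
    params = PhysicalParams(D=1e-10, a=1.0, rho=1.0, Cth=25 / 1e-4, h=1e-4)
    return params, geom


@pytest.fixture
def fig2_system():
    """Half-space benchmark: Cth/(a rho) = 2/(pi 2e-6) s/m -> v=2 µm/s."""
    geom = Geometry(2, 3)
    params = PhysicalParams(D=1e-10, a=1.0, rho=1.0, Cth=2 / (np.pi * 2e-6))
    return params, geom


@pytest.fixture
def neutrophil_params():
    """Fitted swarming conditions: Cth/(a rho)=3.66e5 s/m, D=1.25e-10 m^2/s."""
    return PhysicalParams(D=1.25e-10, a=40.0, rho=(50e-6) ** -2,
                          Cth=3.66e5 * 40.0 * (50e-6) ** -2,
                          h=2e-3, H=10e-6, d=50e-6)
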
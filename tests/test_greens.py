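"""Kernel and quadrature checks against brute-force oracles.

The closed-form band integrals (erf forms, Rician CDF) are validated
against direct numerical integration of the raw kernels, and the colony
concentrations against independent closed forms (uniform sources,
steady-state ball).
"""

import numpy as np
import pytest
from scipy import integrate, special

from relaywave import (Geometry, concentration_from_colony,
                       concentration_from_front, point_propagator,
                       ring_kernel, steady_state_colony, wave_speed)
from relaywave.front import FrontTrajectory
from relaywave.greens import (colony_concentration_nd, source_band,
                              steady_state_nd)

from conftest import params_for

D = 1e-10


class TestPointPropagator:
    def test_normalization_point(self):
        # m=1: value at x=0 is (4 pi D tau)^(-1/2)
        tau = 1.0 / (4 * np.pi * D)
        assert point_propagator(1, 0.0, tau, D) == pytest.approx(1.0)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_conserves_unit_mass(self, m):
        tau = 7.0
        shell = {1: 2.0, 2: 2 * np.pi, 3: 4 * np.pi}[m]
        width = np.sqrt(4 * D * tau)
        total, _ = integrate.quad(
            lambda x: shell * x ** (m - 1) * point_propagator(m, x, tau, D),
            0, 40 * width, limit=200)
        assert total == pytest.approx(1.0, rel=1e-8)

    def test_characteristic_decay(self):
        tau = 3.0
        x = np.sqrt(4 * D * tau)
        expect = np.exp(-1) * (4 * np.pi * D * tau) ** -1.5
        assert point_propagator(3, x, tau, D) == pytest.approx(expect)

    def test_rejects_nonpositive_tau(self):
        with pytest.raises(ValueError):
            point_propagator(2, 1.0, 0.0, D)


class TestRingKernel:
    @pytest.mark.parametrize("pair", [(2, 2), (2, 3), (3, 3)], ids=str)
    def test_matches_brute_shell_integral(self, pair):
        """Angular quadrature of the point propagator over the source shell."""
        geom = Geometry(*pair)
        h = 1e-4
        r, R, tau = 140e-6, 90e-6, 11.0
        n, m = pair
        if n == 2:
            def integrand(theta):
                d = np.sqrt(r * r + R * R - 2 * r * R * np.cos(theta))
                return R * point_propagator(m, d, tau, D)
            brute, _ = integrate.quad(integrand, 0, 2 * np.pi, limit=200)
        else:
            def integrand(theta):
                d = np.sqrt(r * r + R * R - 2 * r * R * np.cos(theta))
                return (2 * np.pi * R ** 2 * np.sin(theta)
                        * point_propagator(m, d, tau, D))
            brute, _ = integrate.quad(integrand, 0, np.pi, limit=200)
        if m > n:
            brute *= 2          # image factor for the half space
        if pair == (2, 2):
            brute /= h          # thin film
        val = ring_kernel(geom, r, R, tau, D, h=h)
        assert val == pytest.approx(brute, rel=1e-8)

    def test_mirror_pair_for_cells_in_1d(self):
        geom = Geometry(1, 1)
        h = 1e-4
        r, R, tau = 30e-6, 110e-6, 5.0
        expect = (point_propagator(1, r - R, tau, D)
                  + point_propagator(1, r + R, tau, D)) / h ** 2
        assert ring_kernel(geom, r, R, tau, D, h=h) == pytest.approx(expect)

    def test_thin_film_center_reduction(self):
        # at r=0 the (2,2) ring kernel is (2 pi R/h) P_2(R, tau): I0(0)=1
        h, R, tau = 1e-4, 70e-6, 2.0
        expect = 2 * np.pi * R / h * point_propagator(2, R, tau, D)
        val = ring_kernel(Geometry(2, 2), 0.0, R, tau, D, h=h)
        assert val == pytest.approx(expect, rel=1e-12)

    def test_halfspace_plane_source_total(self):
        # integral over all source radii: uniform plane into a half space
        tau = 9.0
        r = 120e-6
        hi = r + 40 * np.sqrt(4 * D * tau)
        total, _ = integrate.quad(
            lambda R: ring_kernel(Geometry(2, 3), r, R, tau, D),
            0, hi, points=[r], limit=200)
        assert total == pytest.approx(2 / np.sqrt(4 * np.pi * D * tau),
                                      rel=1e-7)

    def test_fullspace_shell_source_total(self):
        tau = 9.0
        r = 120e-6
        hi = r + 40 * np.sqrt(4 * D * tau)
        total, _ = integrate.quad(
            lambda R: ring_kernel(Geometry(3, 3), r, R, tau, D),
            0, hi, points=[r], limit=200)
        assert total == pytest.approx(1.0, rel=1e-7)

    def test_no_overflow_at_small_tau(self):
        # naive I0 would overflow for r R / 2 D tau >~ 700
        val = ring_kernel(Geometry(2, 3), 1e-3, 1e-3, 1e-4, D)
        assert np.isfinite(val) and val > 0


class TestSourceBand:
    """Closed-form R-band integrals vs brute quadrature of the raw kernels."""

    @pytest.mark.parametrize("pair,r,b,tau", [
        ((1, 1), 3.0, 2.0, 1.5), ((1, 2), 0.5, 2.0, 0.7),
        ((2, 2), 4.0, 4.0, 2.0), ((2, 3), 10.0, 10.0, 0.9),
        ((2, 3), 35.0, 30.0, 0.01), ((3, 3), 2.0, 2.5, 3.0),
    ], ids=str)
    def test_band_matches_brute(self, pair, r, b, tau):
        # brute integrand assembled directly from the heat kernel, in the
        # same natural units (D=1) and with the same geometric prefactors
        # that source_band folds in
        n, m = pair

        def brute_kernel(R):
            if n == 1:
                val = (point_propagator(m, r - R, tau, 1.0)
                       + point_propagator(m, r + R, tau, 1.0))
                if m == 2:
                    val *= 2 * (np.pi / 2)      # image factor x nondim pref
                return val
            if n == 2:
                s2 = 2 * tau
                val = (R / s2) * special.ive(0, r * R / s2) * np.exp(
                    -((r - R) ** 2) / (2 * s2))
                if m == 3:
                    val *= np.pi / np.sqrt(4 * np.pi * tau)
                return val
            # n == 3 shell
            l2 = 4 * tau
            return (R / r) / np.sqrt(4 * np.pi * tau) * (
                np.exp(-(r - R) ** 2 / l2) - np.exp(-(r + R) ** 2 / l2))

        brute, _ = integrate.quad(brute_kernel, 0, b, limit=400)
        val = source_band(pair, r, b, tau)
        assert val == pytest.approx(brute, rel=2e-6, abs=1e-12)

    def test_large_snr_branch_continuity(self):
        # the Gaussian approximation takes over at SNR^2 = 1e4
        r = 120.0
        for tau in (r * r / 2 / 9.9e3, r * r / 2 / 1.01e4):
            a = source_band((2, 2), r, r, tau)
            assert 0.4 < a < 0.6


class TestColonyConcentration:
    def test_channel_center_linear_growth(self):
        # (1,1), observer at the center of a huge colony: c = (a rho/h^2) t
        geom = Geometry(1, 1)
        p = params_for(geom, v=1e-6)
        t = 50.0
        c = concentration_from_colony(0.0, t, 1.0, p, geom)
        assert c == pytest.approx(p.a * p.rho * t / p.h ** 2, rel=1e-7)

    def test_halfspace_plane_sqrt_growth(self):
        # (2,3), r=0, huge colony: c = 2 a rho sqrt(t/(pi D))
        geom = Geometry(2, 3)
        p = params_for(geom, v=1e-6)
        t = 200.0
        c = concentration_from_colony(1e-9, t, 1.0, p, geom)
        assert c == pytest.approx(2 * p.a * p.rho * np.sqrt(t / (np.pi * p.D)),
                                  rel=1e-6)

    def test_ball_steady_state_surface(self):
        # (3,3): steady state at the surface of an emitting ball is
        # a rho ri^2 / 3 D (Poisson equation oracle)
        geom = Geometry(3, 3)
        p = params_for(geom, v=1e-6)
        ri = 120e-6
        c = steady_state_colony(ri, ri, p, geom)
        assert c == pytest.approx(p.a * p.rho * ri ** 2 / (3 * p.D), rel=1e-6)

    def test_disk_steady_state_rim(self):
        # (2,3): steady state at the rim of an emitting disk is
        # 2 a rho ri / (pi D) (disk-potential oracle)
        geom = Geometry(2, 3)
        p = params_for(geom, v=1e-6)
        ri = 80e-6
        c = steady_state_colony(ri, ri, p, geom)
        assert c == pytest.approx(2 * p.a * p.rho * ri / (np.pi * p.D),
                                  rel=1e-5)

    def test_steady_state_rejected_for_open_environments(self):
        with pytest.raises(ValueError):
            steady_state_nd((2, 2), 1.0, 1.0)

    def test_conservation_in_channel(self):
        # emitted molecules a rho (2 ri) t  ==  integral of c over the channel
        geom = Geometry(1, 1)
        p = params_for(geom, v=1e-6)
        ri, t = 100e-6, 400.0
        L = 1e-3 + np.sqrt(4 * p.D * t) * 8
        xs = np.linspace(0, L, 400)
        c = concentration_from_colony(xs, t, ri, p, geom)
        total = 2 * np.trapezoid(c, xs) * p.h ** 2
        assert total == pytest.approx(p.a * p.rho * 2 * ri * t, rel=5e-3)


class TestConcentrationFromFront:
    def test_static_front_reduces_to_colony(self):
        geom = Geometry(2, 3)
        p = params_for(geom, v=2e-6)
        ri = 200e-6
        # a front pinned at zero radius contributes nothing beyond the colony
        traj = FrontTrajectory(times=np.array([0.0, 500.0]),
                               radii=np.array([0.0, 0.0]), ri=ri, dt=500.0)
        r, t = 300e-6, 300.0
        a = concentration_from_front(r, t, traj, ri, p, geom)
        b = concentration_from_colony(r, t, ri, p, geom)
        assert a == pytest.approx(b, rel=1e-5)

    def test_uncovered_time_raises(self):
        geom = Geometry(2, 3)
        p = params_for(geom, v=2e-6)
        traj = FrontTrajectory(times=np.array([10.0, 20.0]),
                               radii=np.array([1e-4, 1.5e-4]), ri=1e-4,
                               dt=10.0)
        with pytest.raises(ValueError, match="cover"):
            concentration_from_front(2e-4, 50.0, traj, 1e-4, p, geom)
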
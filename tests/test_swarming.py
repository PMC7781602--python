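"""Swarming information fronts: prediction, fitting, model discrimination."""

import numpy as np
import pytest

from relaywave import swarming
from relaywave.swarming import (FrontObservations, SwarmFit, fit_front,
                                gradient_profiles,
                                match_simple_diffusion_threshold,
                                predict_front, synth_front_map)

Q_TRUE = 3.66e5        # Cth/(a rho), s/m — fitted swarming value
D_TRUE = 1.25e-10      # m^2/s
RI = 100e-6


class TestPredictFront:
    def test_relay_front_is_convex(self):
        traj = predict_front(Q_TRUE, D_TRUE, RI, 500.0)
        # accelerating toward the asymptotic speed: second differences >= 0
        # (allow root-finder noise at one grid step)
        d2 = np.diff(traj.radii, 2)
        assert np.mean(d2 >= -1e-9) > 0.99
        v_late = np.polyfit(traj.times[-20:], traj.radii[-20:], 1)[0]
        v_early = np.polyfit(traj.times[:20], traj.radii[:20], 1)[0]
        assert v_late > v_early

    def test_diffusion_front_is_concave(self):
        traj = predict_front(2.91e4, D_TRUE, RI, 500.0,
                             model="simple_diffusion")
        inc = np.diff(traj.radii)
        assert inc[-1] < 0.5 * np.max(inc[1:])

    def test_late_slope_matches_speed_relation(self):
        # the asymptote 2/(pi q) is approached slowly (~1/r transient); by
        # 80 D/v^2 (~3300 s) the slope is within 3%
        T = D_TRUE / (2 / (np.pi * Q_TRUE)) ** 2
        traj = predict_front(Q_TRUE, D_TRUE, RI, 80 * T)
        sel = traj.times >= 72 * T
        slope = np.polyfit(traj.times[sel], traj.radii[sel], 1)[0]
        assert slope == pytest.approx(2 / (np.pi * Q_TRUE), rel=0.03)

    def test_unreachable_threshold_never_leaves_target(self):
        # very high threshold: the colony is subcritical -> no relay front
        with pytest.raises(RuntimeError):
            predict_front(1e8, D_TRUE, RI, 500.0)


class TestFitFront:
    def test_noiseless_self_fit_recovers_exactly(self):
        truth = predict_front(Q_TRUE, D_TRUE, RI, 500.0)
        ts = np.linspace(60.0, 480.0, 10)
        obs = FrontObservations(times=ts, radii=truth.radius_at(ts))
        fit = fit_front(obs, RI, initial_guess=(2.5e5, 2e-10))
        assert fit.cth_over_arho == pytest.approx(Q_TRUE, rel=5e-3)
        assert fit.D == pytest.approx(D_TRUE, rel=5e-3)
        assert fit.residual < 1e-6

    def test_implied_speed_identity(self):
        fit = SwarmFit(cth_over_arho=Q_TRUE, D=D_TRUE, residual=0.0)
        assert fit.implied_v == pytest.approx(2 / (np.pi * Q_TRUE), rel=1e-14)

    def test_noisy_recovery_within_ten_percent(self):
        _, obs = synth_front_map(noise=0.05, seed=3)
        fit = fit_front(obs, RI)
        assert fit.cth_over_arho == pytest.approx(Q_TRUE, rel=0.10)
        assert fit.D == pytest.approx(D_TRUE, rel=0.10)

    def test_too_few_points_rejected(self):
        obs = FrontObservations(times=np.array([100.0, 200.0, 300.0]),
                                radii=np.array([1e-4, 2e-4, 3e-4]))
        with pytest.raises(ValueError):
            fit_front(obs, RI)

    def test_model_discrimination(self):
        # data generated by a pure-diffusion truth is fit far better by the
        # diffusion model than by the relay model
        truth = predict_front(2.91e4, D_TRUE, RI, 500.0,
                              model="simple_diffusion")
        ts = np.linspace(80.0, 480.0, 9)
        obs = FrontObservations(times=ts, radii=truth.radius_at(ts))
        relay_fit = fit_front(obs, RI, initial_guess=(1e5, 1e-10))
        diff_fit = fit_front(obs, RI, initial_guess=(1e5, 1e-10),
                             model="simple_diffusion")
        assert relay_fit.residual > 3 * diff_fit.residual


class TestMatchedDiffusionThreshold:
    def test_monotone_in_match_time(self):
        # the relay front pulls away, so matching it at a later time needs
        # ever more sensitive diffusion-model cells (a smaller threshold)
        fit = SwarmFit(cth_over_arho=Q_TRUE, D=D_TRUE, residual=0.0)
        q300 = match_simple_diffusion_threshold(fit, RI, 300.0)
        q500 = match_simple_diffusion_threshold(fit, RI, 500.0)
        assert q500 < q300

    def test_matched_front_actually_matches(self):
        fit = SwarmFit(cth_over_arho=Q_TRUE, D=D_TRUE, residual=0.0)
        q = match_simple_diffusion_threshold(fit, RI, 400.0)
        relay = predict_front(Q_TRUE, D_TRUE, RI, 400.0)
        diff = predict_front(q, D_TRUE, RI, 400.0, model="simple_diffusion")
        assert diff.radius_at(400.0) == pytest.approx(relay.radius_at(400.0),
                                                      rel=1e-3)


# gradient profiles at the diffusion-match time (500 s, fronts coincide) and
# twice that, by when the relay front has pulled far ahead
@pytest.fixture(scope="module")
def profiles():
    q_diff = 2.91e4
    return gradient_profiles((Q_TRUE, D_TRUE), (q_diff, D_TRUE), RI,
                             times=[500.0, 1000.0],
                             r_grid=np.linspace(25e-6, 2.0e-3, 250))


class TestGradientProfiles:
    def test_relay_steeper_inside_front(self, profiles):
        # just inside the relay front the relay gradient dominates the
        # diffusion model's at the same locations
        for i, t in enumerate(profiles.times):
            rf = profiles.relay_front[i]
            sel = (profiles.r > 0.6 * rf) & (profiles.r < 0.95 * rf)
            relay_mag = np.abs(profiles.relay[i][sel])
            diff_mag = np.abs(profiles.diffusion[i][sel])
            assert np.all(relay_mag > diff_mag)

    def test_both_vanish_far_beyond_fronts(self, profiles):
        # a few natural lengths past the front both gradients have decayed
        # to a small fraction of their inside-the-wave values
        i = len(profiles.times) - 1
        rf = profiles.relay_front[i]
        L = D_TRUE / (2 / (np.pi * Q_TRUE))   # D/v
        far = profiles.r > rf + 5 * L
        near = (profiles.r > 0.5 * rf) & (profiles.r < 0.9 * rf)
        assert np.max(np.abs(profiles.relay[i][far])) < 0.05 * np.max(
            np.abs(profiles.relay[i][near]))
        assert np.max(np.abs(profiles.diffusion[i][far])) < 0.05 * np.max(
            np.abs(profiles.diffusion[i][near]))

    def test_relay_gradient_decays_only_modestly(self, profiles):
        # across the inner half of the wave the relay gradient varies by
        # less than an order of magnitude, unlike the collapsing profile of
        # the stalled diffusion model
        i = len(profiles.times) - 1
        rf = profiles.relay_front[i]
        sel = (profiles.r > 0.45 * rf) & (profiles.r < 0.9 * rf)
        relay_mag = np.abs(profiles.relay[i][sel])
        relay_ratio = np.max(relay_mag) / np.min(relay_mag)
        assert relay_ratio < 10.0
        diff_mag = np.abs(profiles.diffusion[i][sel])
        diff_ratio = np.max(diff_mag) / np.min(diff_mag)
        assert diff_ratio > 3 * relay_ratio


class TestSynthFrontMap:
    def test_fixed_seed_is_bit_identical(self):
        m1, o1 = synth_front_map(seed=11)
        m2, o2 = synth_front_map(seed=11)
        np.testing.assert_array_equal(m1.values, m2.values)
        np.testing.assert_array_equal(o1.radii, o2.radii)

    def test_different_seed_differs(self):
        m1, _ = synth_front_map(seed=11)
        m2, _ = synth_front_map(seed=12)
        assert not np.array_equal(m1.values, m2.values)

    def test_zero_noise_extraction_within_one_bin(self):
        cmap, obs = synth_front_map(noise=0.0, seed=0)
        truth = predict_front(Q_TRUE, D_TRUE, RI, 500.0)
        bin_width = cmap.r_bins[1] - cmap.r_bins[0]
        true_r = np.asarray(truth.radius_at(obs.times))
        assert np.all(np.abs(obs.radii - true_r) <= bin_width)

    def test_values_clipped_to_index_range(self):
        cmap, _ = synth_front_map(noise=0.5, seed=5)
        assert np.all(cmap.values <= 1.0) and np.all(cmap.values >= -1.0)
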
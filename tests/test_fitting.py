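"""Offset estimation, Poisson-MLE decay fits, lifetime maps, time courses."""

import numpy as np
import pytest

from flimfret.fitting import (
    OffsetEstimationError,
    estimate_offset,
    fit_decay,
    fret_photon_fraction,
    lifetime_map,
    response_amplitude,
    roi_timecourse,
)
from flimfret.model import (
    DecayParams,
    PhotonHistogram,
    expected_counts,
    mean_lifetime,
)
from flimfret.simulate import simulate_flim_image, simulate_histogram


def _expected_hist(params, irf, total=1e7):
    mu = expected_counts(params, irf, total=total)
    return PhotonHistogram(np.round(mu), irf.channel_width, period=irf.period,
                           allowed_n_channels=())


def _circular_diff(a, b, period=12.5):
    return (a - b + period / 2) % period - period / 2


class TestEstimateOffset:
    def test_null_offset_recovered(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.7, t0=0.0)
        h = simulate_histogram(params, irf_gauss, 1e6, seed=1)
        t0 = estimate_offset(h, irf_gauss)
        assert abs(_circular_diff(t0, 0.0)) < irf_gauss.channel_width / 2

    def test_shift_equivariance(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.6, t0=1.0)
        h = simulate_histogram(params, irf_gauss, 1e6, seed=2)
        t0_a = estimate_offset(h, irf_gauss)
        shifted = PhotonHistogram(np.roll(h.counts, 2), h.channel_width,
                                  period=h.period, allowed_n_channels=())
        t0_b = estimate_offset(shifted, irf_gauss)
        assert _circular_diff(t0_b, t0_a) == pytest.approx(
            2 * irf_gauss.channel_width, abs=0.02)

    def test_known_offset_recovered_within_half_channel(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.7, t0=1.5)
        h = simulate_histogram(params, irf_gauss, 1e6, seed=3)
        t0 = estimate_offset(h, irf_gauss)
        assert abs(_circular_diff(t0, 1.5)) < 0.5 * irf_gauss.channel_width

    def test_too_few_photons_signals_failure(self, irf_gauss):
        h = simulate_histogram(DecayParams(1.0, 0.7), irf_gauss, 100, seed=0)
        with pytest.raises(OffsetEstimationError):
            estimate_offset(h, irf_gauss)


class TestFitDecay:
    def test_pure_free_donor_noiseless(self, irf_gauss):
        h = _expected_hist(DecayParams(1.0, p_free=1.0, t0=0.5), irf_gauss)
        fr = fit_decay(h, irf_gauss, t0=0.5)
        assert fr.params.p_fret < 1e-6
        assert fr.converged

    def test_parameter_recovery_high_counts(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.6, t0=1.5)
        h = simulate_histogram(params, irf_gauss, 1e6, seed=4)
        fr = fit_decay(h, irf_gauss, t0=1.5)
        assert fr.params.p_fret == pytest.approx(0.4, abs=0.01)

    def test_matches_grid_search_oracle(self, irf_gauss):
        # exhaustive likelihood scan on a 1e-3 grid, independent of the
        # optimizer path
        from flimfret.fitting import _component_pair, _profiled_deviance

        params = DecayParams(1.0, p_free=0.55, t0=1.0)
        h = simulate_histogram(params, irf_gauss, 1e5, seed=5)
        fr = fit_decay(h, irf_gauss, t0=1.0)
        s_free, s_fret = _component_pair(irf_gauss, 1.0, 2.6, 1.1)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-3)
        devs = [_profiled_deviance(p, h.counts.astype(float), h.total,
                                   s_free, s_fret) for p in grid]
        p_grid = grid[int(np.argmin(devs))]
        assert abs(fr.params.p_fret - p_grid) <= 1e-3

    def test_scale_invariance_across_photon_budgets(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.7, t0=0.5)
        for n in (1e4, 1e5, 1e6):
            fr = fit_decay(_expected_hist(params, irf_gauss, total=n),
                           irf_gauss, t0=0.5)
            assert fr.params.p_fret == pytest.approx(0.3, abs=0.005)

    def test_low_count_histogram_rejected(self, irf_gauss):
        h = simulate_histogram(DecayParams(1.0, 0.7), irf_gauss, 10, seed=0)
        with pytest.raises(ValueError):
            fit_decay(h, irf_gauss)

    def test_full_mode_recovers_lifetimes(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.6, tau_free=2.6, tau_fret=1.1,
                             t0=1.0)
        h = simulate_histogram(params, irf_gauss, 1e6, seed=6)
        fr = fit_decay(h, irf_gauss, t0=1.0, mode="full")
        assert fr.params.tau_free == pytest.approx(2.6, abs=0.15)
        assert fr.params.tau_fret == pytest.approx(1.1, abs=0.15)
        assert fr.params.p_fret == pytest.approx(0.4, abs=0.05)

    def test_wls_cross_check_agrees_at_high_counts(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.6, t0=0.5)
        h = simulate_histogram(params, irf_gauss, 1e6, seed=7)
        a = fit_decay(h, irf_gauss, t0=0.5, loss="poisson")
        b = fit_decay(h, irf_gauss, t0=0.5, loss="wls")
        assert a.params.p_fret == pytest.approx(b.params.p_fret, abs=0.01)


class TestFretPhotonFraction:
    @pytest.mark.parametrize("p_free,expected", [(1.0, 0.0), (0.0, 1.0)])
    def test_endpoints(self, p_free, expected):
        assert fret_photon_fraction(
            DecayParams(1.0, p_free=p_free)) == expected

    def test_arithmetic_oracle_and_ordering(self):
        # p_fret=0.5: 0.5*1.1 / (0.5*2.6 + 0.5*1.1) = 0.55/1.85
        p = DecayParams(1.0, p_free=0.5)
        assert fret_photon_fraction(p) == pytest.approx(0.2972972972972973)
        # shorter-lived FRET species emits fewer photons than its amplitude
        assert fret_photon_fraction(p) < p.p_fret

    def test_strictly_increasing_in_p_fret(self):
        grid = np.linspace(0, 1, 51)
        vals = [fret_photon_fraction(DecayParams(1.0, p_free=1 - pf))
                for pf in grid]
        assert np.all(np.diff(vals) > 0)


class TestLifetimeMap:
    def _uniform_stack(self, irf, p_free=0.7, photons=3000, shape=(5, 5)):
        phantom = np.ones(shape, dtype=int)
        return simulate_flim_image(
            phantom, {1: DecayParams(1.0, p_free=p_free)}, photons, irf,
            seed=21)

    def test_uniform_phantom_mean_near_truth(self, irf_gauss):
        stack = self._uniform_stack(irf_gauss)
        lm = lifetime_map(stack, irf_gauss, t0=0.0)
        truth = mean_lifetime(DecayParams(1.0, 0.7), "photon")
        assert lm.lifetime.mean() == pytest.approx(truth, abs=0.05)

    def test_background_pixels_masked(self, irf_gauss):
        phantom = np.zeros((4, 4), dtype=int)
        phantom[0, 0] = 1
        stack = simulate_flim_image(phantom, {1: DecayParams(1.0, 0.7)},
                                    3000, irf_gauss, seed=0)
        lm = lifetime_map(stack, irf_gauss, t0=0.0)
        assert lm.mask.sum() == 15 and not lm.mask[0, 0]
        assert lm.lifetime.count() == 1  # only one unmasked value

    def test_two_region_ordering(self, irf_gauss):
        phantom = np.ones((4, 8), dtype=int)
        phantom[:, 4:] = 2
        stack = simulate_flim_image(
            phantom, {1: DecayParams(1.0, 0.85), 2: DecayParams(1.0, 0.45)},
            3000, irf_gauss, seed=13)
        lm = lifetime_map(stack, irf_gauss, t0=0.0)
        assert (lm.lifetime[:, :4].mean() > lm.lifetime[:, 4:].mean())

    def test_fast_and_slow_paths_agree(self, irf_gauss):
        stack = self._uniform_stack(irf_gauss, photons=20_000, shape=(3, 3))
        fast = lifetime_map(stack, irf_gauss, t0=0.0, method="empirical")
        slow = lifetime_map(stack, irf_gauss, t0=0.0, method="fit")
        rel = np.abs(fast.lifetime / slow.lifetime - 1.0)
        assert float(rel.max()) < 0.02

    def test_binning_pools_photons(self, irf_gauss):
        stack = self._uniform_stack(irf_gauss, photons=40, shape=(4, 4))
        lm1 = lifetime_map(stack, irf_gauss, t0=0.0, photon_threshold=100)
        lm2 = lifetime_map(stack, irf_gauss, t0=0.0, photon_threshold=100,
                           binning=2)
        assert lm1.mask.all() and not lm2.mask.any()

    def test_invalid_threshold_rejected(self, irf_gauss):
        with pytest.raises(ValueError):
            lifetime_map(np.zeros((2, 2, 64)), irf_gauss, 0.0,
                         photon_threshold=0)


class TestRoiTimecourse:
    def test_constant_frames_have_null_deltas(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.7, t0=0.5)
        frames = [simulate_histogram(params, irf_gauss, 1e5, seed=s)
                  for s in range(8)]
        df = roi_timecourse(frames, irf_gauss, t0=0.5,
                            baseline_window=slice(0, 4))
        assert np.all(np.abs(df["dlifetime"]) < 0.03)
        assert np.all(np.abs(df["dp_fret"]) < 0.02)

    def test_empty_baseline_rejected(self, irf_gauss):
        params = DecayParams(1.0, p_free=0.7)
        frames = [simulate_histogram(params, irf_gauss, 1e4, seed=0)]
        with pytest.raises(ValueError):
            roi_timecourse(frames, irf_gauss, t0=0.0,
                           baseline_window=slice(0, 0))

    def test_response_amplitude_definition(self):
        v = np.array([1.0, 1.0, 2.0, 2.0])
        assert response_amplitude(v, slice(0, 2), slice(2, 4)) == 1.0
        with pytest.raises(ValueError):
            response_amplitude(v, slice(0, 0), slice(2, 4))
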
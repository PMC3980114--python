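"""Synthetic TCSPC, reporter-kinetics, image and FRAP generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flimfret.model import DecayParams, empirical_mean_lifetime, mean_lifetime
from flimfret.simulate import (
    CompartmentScenario,
    Epoch,
    FRAPSimConfig,
    KineticRates,
    agonist_scenario,
    default_scenario,
    frap_recovery_curve,
    simulate_flim_image,
    simulate_flim_timecourse,
    simulate_frap,
    simulate_histogram,
    simulate_reporter_kinetics,
)


class TestSimulateHistogram:
    def test_zero_photons_gives_empty_histogram(self, irf_gauss, params_mixed):
        h = simulate_histogram(params_mixed, irf_gauss, 0, seed=0)
        assert h.total == 0

    def test_total_count_statistics(self, irf_gauss, params_mixed):
        # mean total over 200 seeds ~ n_photons (Poisson)
        n = 10_000
        totals = [simulate_histogram(params_mixed, irf_gauss, n, seed=s).total
                  for s in range(200)]
        assert np.mean(totals) == pytest.approx(n, abs=3 * np.sqrt(n / 200))

    def test_multinomial_mode_fixes_total(self, irf_gauss, params_mixed):
        h = simulate_histogram(params_mixed, irf_gauss, 5000, seed=1,
                               mode="multinomial")
        assert h.total == 5000

    def test_seed_determinism(self, irf_gauss, params_mixed):
        a = simulate_histogram(params_mixed, irf_gauss, 1e4, seed=42)
        b = simulate_histogram(params_mixed, irf_gauss, 1e4, seed=42)
        assert np.array_equal(a.counts, b.counts)

    def test_large_n_lifetime_consistency(self, irf_delta, params_mixed):
        h = simulate_histogram(params_mixed, irf_delta, 2e6, seed=7)
        est = empirical_mean_lifetime(h, 0.0, lifetimes=(2.6, 1.1))
        assert est == pytest.approx(mean_lifetime(params_mixed, "photon"),
                                    abs=0.015)


class TestReporterKinetics:
    def test_absorbing_state(self):
        epochs = [Epoch("baseline", 10.0, KineticRates(0.0, 0.5))]
        p = simulate_reporter_kinetics(epochs, 0.0, np.linspace(0, 9, 50))
        assert np.all(p == 0.0)

    def test_long_time_steady_state(self):
        rates = KineticRates(0.3, 0.1)
        epochs = [Epoch("forskolin", 1000.0, rates)]
        p = simulate_reporter_kinetics(epochs, 0.0, [999.0])
        assert p[0] == pytest.approx(rates.p_inf, abs=1e-9)

    def test_closed_form_matches_euler_oracle(self):
        # fine-step forward-Euler integration of dp/dt = k_pka(1-p) - k_phos p
        k_pka, k_phos, p0, T = 0.12, 0.05, 0.2, 30.0
        dt = 1e-4
        p = p0
        for _ in range(int(T / dt)):
            p += dt * (k_pka * (1 - p) - k_phos * p)
        epochs = [Epoch("agonist", 2 * T, KineticRates(k_pka, k_phos))]
        closed = simulate_reporter_kinetics(epochs, p0, [T])[0]
        assert closed == pytest.approx(p, abs=1e-6)

    def test_piecewise_epochs_are_continuous(self):
        epochs = [Epoch("baseline", 50.0, KineticRates(0.01, 0.05)),
                  Epoch("forskolin", 50.0, KineticRates(0.2, 0.05))]
        t = np.linspace(0, 99.9, 2000)
        p = simulate_reporter_kinetics(epochs, 0.1, t)
        assert np.all(np.abs(np.diff(p)) < 0.02)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            KineticRates(-0.1, 0.5)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1),
                              st.floats(0.1, 100)), min_size=1, max_size=5),
           st.floats(0, 1))
    def test_fraction_stays_in_unit_interval(self, schedule, p_init):
        epochs = [Epoch("baseline", d, KineticRates(ka, kp))
                  for ka, kp, d in schedule]
        total = sum(e.duration for e in epochs)
        p = simulate_reporter_kinetics(epochs, p_init,
                                       np.linspace(0, total * 0.999, 67))
        assert np.all((p >= 0) & (p <= 1))


class TestFlimTimecourse:
    def test_null_scenario_is_flat(self, irf_gauss):
        rates = KineticRates(0.05, 0.05)
        scen = CompartmentScenario(
            compartments={"cytoplasm": (Epoch("baseline", 100.0, rates),
                                        Epoch("forskolin", 100.0, rates))},
            photons_per_frame=5e4)
        tc = simulate_flim_timecourse(scen, irf_gauss, seed=5)["cytoplasm"]
        assert np.ptp(tc.p_fret_true) < 1e-12
        taus = [empirical_mean_lifetime(h, 0.0, lifetimes=(2.6, 1.1))
                for h in tc.histograms]
        assert np.std(taus) < 0.03

    def test_ground_truth_emitted_and_consistent(self, irf_gauss):
        tc = simulate_flim_timecourse(default_scenario(), irf_gauss, seed=2)
        c = tc["cytoplasm"]
        assert len(c.histograms) == len(c.times) == len(c.p_true)
        assert np.allclose(c.p_fret_true, c.scenario.p_fret_of(c.p_true))

    def test_nucleus_lags_cytoplasm_under_agonist(self, irf_gauss):
        # same steady-state target, tenfold slower nuclear rates: the
        # nucleus crosses half-maximal response later (closed-form truth)
        tc = simulate_flim_timecourse(agonist_scenario(), irf_gauss, seed=3)

        def half_max_time(c):
            p = c.p_true
            target = p[0] + 0.5 * (p[-1] - p[0])
            return c.times[np.argmax(p >= target)]

        assert half_max_time(tc["nucleus"]) > half_max_time(tc["cytoplasm"])

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            Epoch("coffee", 10.0, KineticRates(0.1, 0.1))
        with pytest.raises(ValueError):
            CompartmentScenario(compartments={
                "mitochondria": (Epoch("baseline", 10.0,
                                       KineticRates(0.1, 0.1)),)})


class TestFlimImage:
    def test_uniform_phantom_lifetimes_cluster_around_truth(self, irf_delta):
        params = DecayParams(1.0, p_free=0.7)
        phantom = np.ones((6, 6), dtype=int)
        stack = simulate_flim_image(phantom, {1: params}, 5000, irf_delta,
                                    seed=9)
        taus = [empirical_mean_lifetime(
                    _hist(stack[i, j], irf_delta), 0.0, lifetimes=(2.6, 1.1))
                for i in range(6) for j in range(6)]
        assert np.mean(taus) == pytest.approx(
            mean_lifetime(params, "photon"), abs=0.05)

    def test_background_pixels_have_zero_counts(self, irf_delta):
        phantom = np.zeros((4, 4), dtype=int)
        phantom[0, 0] = 1
        stack = simulate_flim_image(phantom, {1: DecayParams(1.0, 0.5)},
                                    1000, irf_delta, seed=0)
        assert stack[1:, :].sum() == 0 and stack[0, 0].sum() > 0

    def test_missing_region_params_rejected(self, irf_delta):
        with pytest.raises(ValueError):
            simulate_flim_image(np.ones((2, 2), dtype=int), {}, 100,
                                irf_delta, seed=0)


def _hist(counts, irf):
    from flimfret.model import PhotonHistogram
    return PhotonHistogram(counts, irf.channel_width, period=irf.period,
                           allowed_n_channels=())


class TestSimulateFrap:
    def test_realized_bleach_depth_in_operating_band(self):
        # default config sits in the 30-50% bleaching band
        res = simulate_frap(FRAPSimConfig(noise_sd=0.0), seed=0)
        tr = res.traces[0]
        depth = 1.0 - tr.fluorescence[tr.time >= 0].min()
        assert 0.30 <= depth <= 0.50

    def test_noiseless_trace_matches_closed_form(self):
        config = FRAPSimConfig(tau_true=400.0, noise_sd=0.0)
        res = simulate_frap(config, seed=1)
        tr = res.traces[0]
        assert np.allclose(tr.fluorescence,
                           frap_recovery_curve(config, tr.time))

    def test_no_bleach_gives_flat_trace(self):
        res = simulate_frap(FRAPSimConfig(bleach_frac=0.0, noise_sd=0.0),
                            seed=2)
        assert np.allclose(res.traces[0].fluorescence, 1.0)

    def test_seed_determinism(self):
        a = simulate_frap(FRAPSimConfig(), seed=3)
        b = simulate_frap(FRAPSimConfig(), seed=3)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.fluorescence, tb.fluorescence)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FRAPSimConfig(bleach_frac=1.5)
        with pytest.raises(ValueError):
            FRAPSimConfig(tau_true=-1.0)
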
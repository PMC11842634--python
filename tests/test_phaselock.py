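"""Analytic signals, PLV, stimulus templates, cross-correlation, phase lag."""

import numpy as np
import pytest

from resplock import simulate_session
from resplock.phaselock import (Correlogram, cross_correlate,
                                estimate_phase_lag, find_correlation_maxima,
                                hilbert_analytic, instantaneous_phase_lag,
                                lattice_delay, make_stimulus_template,
                                peak_delay, peak_delay_histogram, plv,
                                sliding_plv, windowed_correlograms)
from resplock.fidelity import window_peak_delays

from conftest import noiseless_config


def fft_analytic_oracle(x):
    """Independent construction: flip negative frequencies in the spectrum."""
    n = len(x)
    spectrum = np.fft.fft(x)
    weights = np.zeros(n)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[n // 2] = 1.0
        weights[1:n // 2] = 2.0
    else:
        weights[1:(n + 1) // 2] = 2.0
    return np.fft.ifft(spectrum * weights)


class TestHilbert:
    def test_matches_fft_oracle_on_random_series(self, rng):
        for _ in range(100):
            x = rng.standard_normal(rng.integers(64, 512))
            got = hilbert_analytic(x)
            expected = fft_analytic_oracle(x)
            assert np.allclose(got.imag, expected.imag, atol=1e-9)
            assert np.allclose(got.envelope, np.abs(expected), atol=1e-9)

    def test_cosine_envelope_and_linear_phase(self):
        fs, f0 = 125.0, 12.5
        t = np.arange(500) / fs
        got = hilbert_analytic(np.cos(2 * np.pi * f0 * t))
        interior = slice(50, 450)
        assert np.allclose(got.envelope[interior], 1.0, atol=1e-2)
        dphi = np.diff(np.unwrap(got.phase[interior]))
        assert np.allclose(dphi, 2 * np.pi * f0 / fs, atol=1e-2)

    def test_zero_input_zero_envelope(self):
        assert np.allclose(hilbert_analytic(np.zeros(64)).envelope, 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hilbert_analytic(np.array([1.0, np.nan] + [0.0] * 10))
        with pytest.raises(ValueError):
            hilbert_analytic(np.ones(4))


class TestPhaseLagAndPLV:
    def test_identical_signals_zero_lag(self, rng):
        a = hilbert_analytic(rng.standard_normal(128))
        assert np.allclose(instantaneous_phase_lag(a, a), 0.0)

    def test_quarter_period_shift_gives_half_pi(self):
        fs, f0 = 125.0, 12.5
        t = np.arange(1000) / fs
        stim = hilbert_analytic(np.sin(2 * np.pi * f0 * t))
        resp = hilbert_analytic(np.sin(2 * np.pi * f0 * t + np.pi / 2))
        lag = instantaneous_phase_lag(resp, stim)
        assert np.allclose(lag[100:900], np.pi / 2, atol=1e-2)

    def test_matches_complex_argument_oracle(self, rng):
        a = hilbert_analytic(rng.standard_normal(256))
        b = hilbert_analytic(rng.standard_normal(256))
        oracle = np.angle(np.exp(1j * a.phase) * np.exp(-1j * b.phase))
        assert np.allclose(instantaneous_phase_lag(a, b), oracle,
                           atol=1e-12)

    def test_length_mismatch(self, rng):
        a = hilbert_analytic(rng.standard_normal(64))
        b = hilbert_analytic(rng.standard_normal(65))
        with pytest.raises(ValueError):
            instantaneous_phase_lag(a, b)

    def test_plv_constant_lag_is_one(self):
        assert plv(np.full(62, 0.7)) == pytest.approx(1.0)

    def test_plv_antipodal_lags_cancel(self):
        assert plv(np.array([0.0, np.pi] * 31)) == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_plv_empty_raises(self):
        with pytest.raises(ValueError):
            plv(np.array([]))

    def test_plv_uniform_lags_match_rayleigh_mean(self, rng):
        # For i.i.d. uniform phases the expected resultant length at N=62
        # is sqrt(pi)/2 / sqrt(N) ~ 0.1125.
        values = [plv(rng.uniform(-np.pi, np.pi, 62)) for _ in range(1000)]
        assert np.mean(values) == pytest.approx(np.sqrt(np.pi) / 2
                                                / np.sqrt(62), abs=0.01)

    def test_plv_invariant_to_common_phase_offset(self, rng):
        lags = rng.uniform(-np.pi, np.pi, 200)
        shifted = np.angle(np.exp(1j * (lags + 1.234)))
        # A global offset added to both signals cancels in the difference;
        # equivalently PLV of the lag series is offset-invariant.
        assert plv(lags) == pytest.approx(plv(shifted), abs=1e-12)


class TestSlidingPLV:
    def test_window_arithmetic_62_samples(self):
        stim = make_stimulus_template()
        series = np.sin(2 * np.pi * 12.5 * np.arange(225) / 125.0)
        out = sliding_plv(series, stim, window_s=0.5)
        assert out.window_samples == 62

    def test_noiseless_locking_near_one(self, small_noiseless_session):
        s = small_noiseless_session
        epoch = s.epochs[1, s.channel_index("O1")]
        out = sliding_plv(epoch, make_stimulus_template())
        # Windows fully inside the mutually active region.
        assert out.values[20:80].min() > 0.99

    def test_white_noise_low_plv(self, rng):
        stim = make_stimulus_template(repetitions=4)
        noise = rng.standard_normal(len(stim.samples))
        out = sliding_plv(noise, stim)
        assert out.values.mean() < 0.3

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValueError):
            sliding_plv(np.zeros(60), make_stimulus_template(),
                        window_s=0.5)


class TestStimulusTemplate:
    def test_active_segment_has_twenty_cycles(self):
        stim = make_stimulus_template()
        active = stim.samples[:200]
        t = np.arange(200) / 125.0
        assert np.allclose(active, np.sin(2 * np.pi * 12.5 * t))
        assert stim.active_s * stim.f0 == pytest.approx(20.0)
        # 20 rising zero-crossings, one per cycle
        rising = np.sum((active[:-1] <= 0) & (active[1:] > 0))
        assert rising == 20

    def test_off_segment_is_25_zero_samples(self):
        stim = make_stimulus_template()
        assert len(stim.samples) == 225
        assert np.allclose(stim.samples[200:], 0.0)

    def test_zero_amplitude(self):
        assert np.allclose(make_stimulus_template(a0=0.0).samples, 0.0)

    def test_repetition_concatenation(self):
        stim = make_stimulus_template(repetitions=3)
        assert len(stim.samples) == 3 * 225
        assert np.allclose(stim.samples[:225], stim.samples[225:450])

    @pytest.mark.parametrize("reps", [0, 151, -2])
    def test_repetitions_out_of_range(self, reps):
        with pytest.raises(ValueError):
            make_stimulus_template(repetitions=reps)


class TestCrossCorrelation:
    def test_matches_brute_force_oracle(self, rng):
        response = rng.standard_normal(500)
        template = make_stimulus_template()
        got = cross_correlate(response, template)
        t = template.samples
        expected = np.array([
            sum(t[j] * response[j + k] for j in range(len(t)))
            for k in range(len(response) - len(t) + 1)
        ])
        assert np.allclose(got.values, expected, rtol=1e-9, atol=1e-9)

    def test_zero_response_zero_correlogram(self):
        got = cross_correlate(np.zeros(500), make_stimulus_template())
        assert np.allclose(got.values, 0.0)

    def test_template_longer_than_response_raises(self):
        with pytest.raises(ValueError):
            cross_correlate(np.zeros(100), make_stimulus_template())

    def test_maxima_spaced_one_flicker_period(self):
        # Noiseless phase-lagged sinusoidal response: successive local
        # maxima separated by 80 ms regardless of the lag value.
        fs, f0 = 125.0, 12.5
        t = np.arange(3 * 225) / fs
        for lag in (0.0, 1.0, 4.05):
            response = np.sin(2 * np.pi * f0 * t + lag)
            c = cross_correlate(response, make_stimulus_template())
            peaks = find_correlation_maxima(
                Correlogram(values=c.values[:225], delays_s=c.delays_s[:225]),
                min_prominence=0.5)
            spacing = np.diff(peaks)
            assert np.allclose(spacing, 0.08, atol=0.008)

    def test_noiseless_maxima_on_the_lattice(self, small_noiseless_session):
        # tau = -delta + 0.08 n with delta = phi_bar / (2 pi F0)
        s = small_noiseless_session
        cfg = s.config
        from resplock.preprocess import BANDS, bandpass_array
        series = bandpass_array(s.continuous(["O1", "O2"]).mean(axis=0),
                                BANDS["F3"], cfg.sampling_rate)
        cors = windowed_correlograms(series, make_stimulus_template(),
                                     s.onsets, cfg.n_samples)
        delays = find_correlation_maxima(cors[3], min_prominence=0.6)
        delta = cfg.phase_lag_rad / (2 * np.pi * cfg.flicker_hz)
        lattice = np.array([n / cfg.flicker_hz - delta for n in range(1, 24)])
        lattice = lattice[(lattice >= 0) & (lattice < cfg.window_s)]
        # At large delays the template mostly overlaps the *next* action
        # window, whose lattice is phase-shifted; assert only where the
        # template still overlaps this window's response.
        near = delays[delays < 0.6]
        assert len(near) >= 3
        for d in near:
            assert np.abs(lattice - d).min() < 1 / cfg.sampling_rate


class TestMaximaDetection:
    def test_single_lobe(self):
        values = np.exp(-0.5 * ((np.arange(100) - 40) / 5.0) ** 2)
        c = Correlogram(values=values, delays_s=np.arange(100) / 125.0)
        assert np.allclose(find_correlation_maxima(c), [40 / 125.0])

    def test_monotone_series_endpoint_only(self):
        c = Correlogram(values=np.arange(50, dtype=float),
                        delays_s=np.arange(50) / 125.0)
        assert np.allclose(find_correlation_maxima(c), [49 / 125.0])

    def test_all_zero_empty(self):
        c = Correlogram(values=np.zeros(20), delays_s=np.arange(20) / 125.0)
        assert len(find_correlation_maxima(c)) == 0

    def test_parabolic_peak_refinement(self):
        # Sampled windowed-cosine peak: interpolation recovers the
        # continuous maximum far better than the sample grid.
        delays = np.arange(50) / 125.0
        true_peak = 0.123
        values = (np.cos(2 * np.pi * 12.5 * (delays - true_peak))
                  * np.exp(-0.5 * ((delays - true_peak) / 0.1) ** 2))
        c = Correlogram(values=values, delays_s=delays)
        assert peak_delay(c) == pytest.approx(true_peak, abs=1e-3)
        assert peak_delay(c, interpolate=False) == pytest.approx(
            true_peak, abs=0.5 / 125.0)


class TestDelayHistogram:
    def test_identical_delays_single_bin(self):
        hist = peak_delay_histogram(np.full(40, 0.272))
        assert (hist.counts > 0).sum() == 1
        assert hist.counts.sum() == 40
        assert hist.modal_zone == pytest.approx(0.272, abs=0.008)

    def test_default_cohort_modal_zone_near_027(self):
        # Default-condition session: most common peak delay within one
        # 8 ms bin of the 0.27 s response delay.
        session = simulate_session(noiseless_config(seed=77))
        delays = window_peak_delays(session)
        hist = peak_delay_histogram(delays)
        assert abs(hist.modal_zone - 0.27) <= 0.008

    def test_uniform_delays_consistent_with_uniformity(self, rng):
        delays = rng.uniform(0.0, 1.8, 400)
        hist = peak_delay_histogram(delays, bin_s=0.1)
        counts = hist.counts
        assert counts.sum() == 400
        # Expected ~22 per bin; the maximum of 18 multinomial cells stays
        # well below 3x the mean with overwhelming probability.
        assert counts.max() < 3 * counts.mean()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            peak_delay_histogram(np.array([]))


class TestPhaseLagEstimate:
    def test_lattice_delays_with_zero_offset(self):
        delays = np.array([n / 12.5 for n in range(1, 6)])
        est = estimate_phase_lag(delays, 12.5)
        assert est.phi_bar == pytest.approx(0.0, abs=1e-9)

    def test_reported_delay_inverts_to_reported_phase(self):
        # Inverting the lattice at the 0.26843 s delay recovers ~4.05 rad.
        est = estimate_phase_lag(np.array([0.26843]), 12.5)
        assert est.phi_bar == pytest.approx(4.05, abs=0.01)
        assert est.delta == pytest.approx(est.phi_bar / (2 * np.pi * 12.5))

    def test_forward_map_matches_inverse(self):
        tau = lattice_delay(4, 12.5, 4.05)
        assert estimate_phase_lag(np.array([tau]), 12.5).phi_bar \
            == pytest.approx(4.05, abs=1e-9)

    @pytest.mark.parametrize("phi", [0.0, np.pi / 2, np.pi,
                                     3 * np.pi / 2, 4.05])
    def test_recovery_of_injected_lag_noiseless(self, phi):
        cfg = noiseless_config(n_episodes=1, actions_per_episode=12,
                               error_prob=0.0, phase_lag_rad=phi, seed=2)
        delays = window_peak_delays(simulate_session(cfg))
        est = estimate_phase_lag(delays, cfg.flicker_hz)
        err = np.angle(np.exp(1j * (est.phi_bar - phi)))
        assert abs(err) < 0.1

    def test_recovery_under_moderate_noise(self):
        cfg = noiseless_config(noise_sigma=5.0, seed=21)
        delays = window_peak_delays(simulate_session(cfg))
        est = estimate_phase_lag(delays, cfg.flicker_hz)
        err = np.angle(np.exp(1j * (est.phi_bar - cfg.phase_lag_rad)))
        assert abs(err) < 0.1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_phase_lag(np.array([]), 12.5)
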
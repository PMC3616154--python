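"""The adaptive tracker: frequency response, recursion, extraction."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from cfctrack import (
    BandDefinition,
    EEGMimicModel,
    SFTParams,
    TimeSeries,
    analytic_signal,
    bandpass,
    beta_for_bandwidth,
    extract_oscillation,
    gen_eeg_mimic_pair,
    sft_response,
    sft_track,
)

TWO_PI = 2 * math.pi


class TestResponse:
    def test_unit_gain_zero_phase_at_center(self):
        for w in [0.1, 0.5, 1.0, 2.0, 3.0]:
            g = sft_response(w, w, beta=0.95)
            assert g == 1.0 + 0.0j

    def test_magnitude_strictly_decreasing_away_from_center(self):
        w_hat = 1.0
        offsets = np.linspace(0.0, math.pi - 1.01, 300)
        mags = np.abs(sft_response(w_hat + offsets, w_hat, beta=0.97))
        assert np.all(np.diff(mags) < 0)

    def test_magnitude_symmetric_around_center(self):
        w_hat = 1.2
        eps = np.array([1e-4, 1e-3, 1e-2])
        up = np.abs(sft_response(w_hat + eps, w_hat, beta=0.97))
        dn = np.abs(sft_response(w_hat - eps, w_hat, beta=0.97))
        assert np.allclose(up, dn, rtol=1e-10)

    def test_beta_matches_numeric_root_finding(self):
        # oracle: solve |H|^2 = 1/2 at the half-bandwidth offset numerically
        fs, bw = 250.0, 2.0
        half = math.pi * bw / fs

        def half_power(beta):
            return abs(sft_response(1.0 + half, 1.0, beta)) ** 2 - 0.5

        beta_numeric = brentq(half_power, 0.5, 1 - 1e-9, xtol=1e-14)
        assert beta_for_bandwidth(bw, fs) == pytest.approx(beta_numeric, abs=1e-10)
        assert beta_for_bandwidth(bw, fs) == pytest.approx(0.975, abs=0.001)


class TestAnalyticSignal:
    def test_real_part_equals_input(self, rng):
        x = rng.normal(size=1000)
        xa = analytic_signal(x)
        assert np.allclose(xa.real, x, atol=1e-10)

    def test_one_sided_spectrum(self, rng):
        x = rng.normal(size=1024)
        spec = np.fft.fft(analytic_signal(x))
        neg = spec[513:]
        assert np.max(np.abs(neg)) < 1e-8 * np.max(np.abs(spec))

    def test_cosine_magnitude_and_phase_slope(self):
        w0 = TWO_PI * 0.1
        n = np.arange(4000)
        xa = analytic_signal(np.cos(w0 * n))
        interior = slice(500, -500)
        assert np.allclose(np.abs(xa[interior]), 1.0, atol=1e-3)
        # linear-fit oracle on the unwrapped phase
        ph = np.unwrap(np.angle(xa))[interior]
        slope = np.polyfit(np.arange(len(ph)), ph, 1)[0]
        assert slope == pytest.approx(w0, rel=1e-4)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            analytic_signal(np.array([1.0]))


class TestTracking:
    def test_pure_tone_is_fixed_point(self):
        w0 = TWO_PI * 0.05
        xa = np.exp(1j * w0 * np.arange(500))
        tc = sft_track(xa, SFTParams(beta=0.975, delta=0.99, omega_init=w0))
        assert np.allclose(tc.omega, w0, atol=1e-12)

    def test_convergence_from_offset_initialization(self):
        w0 = TWO_PI * 0.05
        xa = np.exp(1j * w0 * np.arange(2000))
        tc = sft_track(xa, SFTParams(beta=0.975, delta=0.99, omega_init=TWO_PI * 0.075))
        assert abs(tc.omega[-1] - w0) < 1e-3 * TWO_PI

    def test_tracks_dominant_tone_under_interference(self):
        n = np.arange(4000)
        xa = np.exp(1j * TWO_PI * 0.05 * n) + 0.1 * np.exp(1j * TWO_PI * 0.2 * n)
        tc = sft_track(xa, SFTParams(beta=0.975, delta=0.99, omega_init=TWO_PI * 0.06))
        assert abs(tc.omega[-1] - TWO_PI * 0.05) < 5e-3 * TWO_PI

    def test_unit_gain_at_tracked_frequency_every_sample(self, rng):
        # the instantaneous filter is exactly transparent at its own centre
        x = rng.normal(size=2000)
        params = SFTParams(beta=0.97, delta=0.99, omega_init=1.0)
        tc = sft_track(analytic_signal(x), params)
        gains = np.array([sft_response(w, w, params.beta) for w in tc.omega[::97]])
        assert np.all(gains == 1.0 + 0.0j)

    def test_bounded_output_on_long_noise_input(self, rng):
        # stability stress: 1e6 samples of white noise stay bounded
        x = rng.normal(size=10**6)
        tc = sft_track(analytic_signal(x), SFTParams(beta=0.99, delta=0.995, omega_init=0.5))
        assert np.all(np.isfinite(tc.y.view(float)))
        assert np.max(np.abs(tc.y)) < 100 * np.max(np.abs(x))
        assert np.all((tc.omega > 0) & (tc.omega < math.pi))

    def test_silent_stretch_holds_frequency(self):
        w0 = TWO_PI * 0.1
        xa = np.concatenate([np.exp(1j * w0 * np.arange(500)), np.zeros(300, complex)])
        tc = sft_track(xa, SFTParams(beta=0.9, delta=0.95, omega_init=w0))
        # after the signal stops, y decays and omega must not produce NaN
        assert np.all(np.isfinite(tc.omega))
        assert tc.omega[-1] == pytest.approx(w0, abs=1e-6)

    def test_equivalent_to_fixed_filter_on_constant_tone(self):
        # on a stationary tone the adaptive filter converges to the fixed
        # one-pole band-pass centred at the true frequency
        w0 = TWO_PI * 0.12
        n = np.arange(3000)
        xa = np.exp(1j * w0 * n)
        beta = 0.97
        tc = sft_track(xa, SFTParams(beta=beta, delta=0.99, omega_init=w0 * 1.2))
        y_fix = np.empty_like(xa)
        acc = 0j
        for i in range(len(xa)):
            acc = beta * np.exp(1j * w0) * acc + (1 - beta) * xa[i]
            y_fix[i] = acc
        assert np.allclose(tc.y[-500:], y_fix[-500:], atol=1e-6)


class TestExtraction:
    def test_band_limited_tone_frequency_recovered(self):
        fs = 250.0
        n = np.arange(1000)
        ts = TimeSeries(np.cos(2 * math.pi * 40.0 / fs * n), fs=fs)
        band = BandDefinition(35, 45)
        x = bandpass(ts, band)
        tc = extract_oscillation(x, band=band)
        assert len(tc.y) == ts.n_samples
        mean_f = tc.frequency_hz[200:].mean()
        assert mean_f == pytest.approx(40.0, abs=0.1)

    def test_zero_signal_flagged_frequency_held(self):
        ts = TimeSeries(np.zeros(600), fs=250.0)
        band = BandDefinition(4, 8)
        tc = extract_oscillation(ts, band=band)
        assert tc.flagged
        assert np.allclose(tc.frequency_hz, band.center_hz)

    def test_relock_after_interference_subsides(self):
        # EEG-mimic signal 2 without noise: the 36 Hz interferer (600-1200 ms)
        # pulls the tracker, which re-locks onto 44 Hz with a short delay
        model = EEGMimicModel(noise_var1=0.0, noise_var2=0.0, seed=5)
        _, x2 = gen_eeg_mimic_pair(model)
        band = BandDefinition(35, 45)
        tc = extract_oscillation(bandpass(x2, band), band=band)
        f = tc.frequency_hz
        t_ms = np.arange(len(f)) / model.fs * 1000.0
        dev_during = np.abs(f[(t_ms >= 800) & (t_ms < 1200)] - 44.0).max()
        dev_after = np.abs(f[(t_ms >= 1450) & (t_ms < 1800)] - 44.0).max()
        assert dev_during > dev_after  # pulled toward the 36 Hz interferer
        assert f[(t_ms >= 1450) & (t_ms < 1800)].mean() == pytest.approx(44.0, abs=1.0)
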
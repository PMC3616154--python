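"""Phase/amplitude extraction, PLV statistics, windows, coefficient validity."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cfctrack import (
    BandDefinition,
    CouplingSpec,
    TimeSeries,
    WindowGrid,
    amplitude_envelope,
    gen_group_dataset,
    instantaneous_phase,
    make_windows,
    pa_plv,
    plv,
    pp_plv,
    valid_coefficients,
    windowed_features,
)

TWO_PI = 2 * math.pi


class TestPhaseAndEnvelope:
    def test_phase_slope_of_cosine(self):
        w0 = TWO_PI * 0.08
        x = np.cos(w0 * np.arange(3000))
        ph = instantaneous_phase(x, unwrap=True)[300:-300]
        slope = np.polyfit(np.arange(len(ph)), ph, 1)[0]
        assert slope == pytest.approx(w0, rel=1e-3)

    def test_complex_input_phase_is_argument(self, rng):
        z = rng.normal(size=100) + 1j * rng.normal(size=100)
        assert np.array_equal(instantaneous_phase(z), np.angle(z))

    def test_sign_flip_shifts_phase_by_pi(self):
        x = np.cos(TWO_PI * 0.1 * np.arange(1000))
        d = instantaneous_phase(-x) - instantaneous_phase(x)
        wrapped = np.angle(np.exp(1j * d))
        assert np.allclose(np.abs(wrapped[100:-100]), math.pi, atol=1e-6)

    def test_all_zero_input_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(100))

    def test_envelope_of_cosine_near_one(self):
        x = np.cos(TWO_PI * 0.1 * np.arange(2000))
        env = amplitude_envelope(x)[200:-200]
        assert np.allclose(env, 1.0, atol=1e-3)

    def test_envelope_recovers_slow_modulation(self):
        n = np.arange(4000)
        a = 1.5 + 0.5 * np.cos(TWO_PI * 0.002 * n)
        x = a * np.cos(TWO_PI * 0.2 * n)
        env = amplitude_envelope(x)[400:-400]
        assert np.allclose(env, a[400:-400], rtol=0.02)

    def test_envelope_of_zero_is_zero(self):
        assert np.allclose(amplitude_envelope(np.zeros(64)), 0.0)


class TestPAPLV:
    def test_constructed_coupling_detected(self):
        fs = 250.0
        n = np.arange(2500)
        w_low = TWO_PI * 6.0 / fs
        w_high = TWO_PI * 40.0 / fs
        low = np.cos(w_low * n)
        high = (1 + 0.9 * np.cos(w_low * n)) * np.cos(w_high * n)
        grid = WindowGrid(win_ms=1000.0, shift_ms=1000.0, fs=fs)
        windows = make_windows(10_000.0, grid)
        vals = pa_plv(low, high, windows, fs=fs, low_band=BandDefinition(4, 8))
        assert np.all(vals >= 0.95)

    def test_independent_phases_match_iid_resultant(self, rng):
        # Monte-Carlo oracle: |mean of N iid unit phasors| at N = 75
        N = 75
        draws = np.abs(
            np.mean(np.exp(1j * rng.uniform(0, TWO_PI, size=(30_000, N))), axis=1)
        )
        expect, se = draws.mean(), draws.std(ddof=1) / math.sqrt(len(draws))
        # independent phase series through the PLV over many windows
        n_win = 800
        d = rng.uniform(0, TWO_PI, size=n_win * N)
        from cfctrack.coupling import Window

        windows = [Window(i * N, (i + 1) * N, float(i)) for i in range(n_win)]
        got = plv(d, windows).mean()
        tol = 3 * math.hypot(se, draws.std(ddof=1) / math.sqrt(n_win))
        assert abs(got - expect) < tol

    def test_perfect_locking_to_own_envelope_phase(self):
        fs = 250.0
        n = np.arange(2000)
        w_low = TWO_PI * 6.0 / fs
        high = (1 + 0.8 * np.cos(w_low * n)) * np.cos(TWO_PI * 40.0 / fs * n)
        from cfctrack.coupling import envelope_phase

        phi_env = envelope_phase(high, fs=fs, low_band=BandDefinition(4, 8))
        # a "low" component whose phase equals the envelope phase locks exactly
        low = np.exp(1j * phi_env)
        val = pa_plv(low, high, fs=fs, low_band=BandDefinition(4, 8))
        assert val == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_envelope_rejected(self):
        x = np.cos(TWO_PI * 0.2 * np.arange(500))
        with pytest.raises(ValueError):
            pa_plv(x, x * 0 + 1e-9, fs=250.0, low_band=BandDefinition(4, 8))


class TestPPPLV:
    def test_identical_phases_unit_plv(self, rng):
        ph = rng.uniform(-math.pi, math.pi, 500)
        assert pp_plv(ph, ph, 1, 1) == pytest.approx(1.0)

    def test_symmetry_in_coefficient_order(self, rng):
        p1 = rng.uniform(-math.pi, math.pi, 300)
        p2 = rng.uniform(-math.pi, math.pi, 300)
        assert pp_plv(p1, p2, 3, 2) == pytest.approx(pp_plv(p2, p1, 2, 3))

    @given(st.integers(1, 9), st.integers(1, 3), st.floats(-3.0, 3.0))
    def test_invariant_to_common_rotation(self, n, m, c):
        rng = np.random.default_rng(99)
        p1 = rng.uniform(-math.pi, math.pi, 200)
        p2 = rng.uniform(-math.pi, math.pi, 200)
        base = pp_plv(p1, p2, n, m)
        rotated = pp_plv(p1 + m * c, p2 + n * c, n, m)
        assert rotated == pytest.approx(base, abs=1e-10)

    @given(st.integers(1, 9), st.integers(1, 3))
    def test_bounded_between_zero_and_one(self, n, m):
        rng = np.random.default_rng(n * 10 + m)
        p1 = rng.uniform(-math.pi, math.pi, 150)
        p2 = rng.uniform(-math.pi, math.pi, 150)
        v = pp_plv(p1, p2, n, m)
        assert 0.0 <= v <= 1.0


class TestValidCoefficients:
    def test_nonoverlapping_scaled_bands_invalid(self):
        assert not valid_coefficients(BandDefinition(1, 4), BandDefinition(35, 45), 2, 1)

    def test_overlapping_scaled_bands_valid(self):
        assert valid_coefficients(BandDefinition(4, 8), BandDefinition(35, 45), 8, 1)

    def test_same_band_one_to_one_valid(self):
        for b in [BandDefinition(1, 4), BandDefinition(35, 45)]:
            assert valid_coefficients(b, b, 1, 1)

    def test_touching_endpoints_do_not_count(self):
        # 2x(1-4) = 2-8 touches 8-12 only at 8
        assert not valid_coefficients(BandDefinition(1, 4), BandDefinition(8, 12), 2, 1)

    def test_spec_constructor_enforces_validity(self):
        with pytest.raises(ValueError):
            CouplingSpec(BandDefinition(1, 4), BandDefinition(35, 45), "phase_phase", 2, 1)


class TestWindows:
    def test_study_grid_has_101_windows(self):
        grid = WindowGrid(win_ms=300, shift_ms=10, fs=250)
        ws = make_windows(2000.0, grid, onset_ms=500.0, center_interval_ms=(0.0, 1000.0))
        assert len(ws) == 101
        assert ws[0].center_ms == 0.0 and ws[-1].center_ms == 1000.0

    def test_window_sample_count_is_75(self):
        grid = WindowGrid(win_ms=300, shift_ms=10, fs=250)
        ws = make_windows(2000.0, grid, onset_ms=500.0, center_interval_ms=(0.0, 1000.0))
        assert all(w.n_samples == 75 for w in ws)

    def test_extreme_shift_gives_first_and_last(self):
        grid = WindowGrid(win_ms=300, shift_ms=700, fs=250)
        ws = make_windows(1000.0, grid)
        assert len(ws) == 2

    def test_window_longer_than_span_rejected(self):
        grid = WindowGrid(win_ms=2000, shift_ms=10, fs=250)
        with pytest.raises(ValueError):
            make_windows(1000.0, grid)


class TestWindowedFeatures:
    def _dataset(self):
        return gen_group_dataset(n_subjects=2, n_trials=1, condition_effect=0.0, seed=4)

    def _spec(self):
        return CouplingSpec(BandDefinition(4, 8), BandDefinition(35, 45), "phase_phase", 8, 1)

    def test_single_window_matches_direct_computation(self):
        ds = self._dataset()
        grid = WindowGrid(fs=ds.fs)
        ws = make_windows(2000.0, grid, onset_ms=500.0, center_interval_ms=(0.0, 0.0))
        spec = self._spec()
        feats = windowed_features(ds, [spec], ws)[spec.label]
        ep = ds.select(subject="S01", condition="A")[0]
        p1 = instantaneous_phase(ep.data[:, 0])
        p2 = instantaneous_phase(ep.data[:, 1])
        direct = pp_plv(p1[ws[0].sl], p2[ws[0].sl], 8, 1)
        assert feats.values[0, 0, 0] == pytest.approx(direct, abs=1e-12)

    def test_frequency_feature_requires_tracking(self):
        ds = self._dataset()
        ws = make_windows(2000.0, WindowGrid(fs=ds.fs), onset_ms=500.0,
                          center_interval_ms=(0.0, 100.0))
        with pytest.raises(ValueError):
            windowed_features(ds, [self._spec()], ws, include_frequency=True)

    def test_duplicated_subject_gives_identical_rows(self):
        ds = self._dataset()
        from cfctrack.containers import Epoch, EpochSet

        clones = []
        for ep in ds.epochs:
            clones.append(Epoch(ep.subject, ep.condition, ep.trial, ep.data.copy()))
            clones.append(Epoch(ep.subject + "_twin", ep.condition, ep.trial, ep.data.copy()))
        ds2 = EpochSet(clones, fs=ds.fs, channel_labels=ds.channel_labels, onset_ms=ds.onset_ms)
        ws = make_windows(2000.0, WindowGrid(fs=ds.fs), onset_ms=500.0,
                          center_interval_ms=(0.0, 200.0))
        spec = self._spec()
        wf = windowed_features(ds2, [spec], ws)[spec.label]
        i1 = wf.subjects.index("S01")
        i2 = wf.subjects.index("S01_twin")
        assert np.allclose(wf.values[:, i1, :], wf.values[:, i2, :])
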
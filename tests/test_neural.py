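"""Hjorth parameters, band amplitudes, bursts, windowed extraction, PSDs."""

import numpy as np
import pytest

from locostate.errors import (ConfigurationError, DegenerateSignalError,
                              InsufficientDataError)
from locostate.neural import (BandDefinition, band_amplitude, burst_metrics,
                              extract_neural_features, hjorth_parameters,
                              sinusoid_mobility, state_psd, welch_psd)

from conftest import make_events, make_recording


def _sine(f, fs, seconds, phase=0.0):
    t = np.arange(int(fs * seconds)) / fs
    return np.sin(2 * np.pi * f * t + phase)


class TestHjorth:
    def test_pure_sinusoid_closed_forms(self):
        x = _sine(10, 200, 10)
        h = hjorth_parameters(x)
        assert abs(h.complexity - 1.0) < 1e-3
        assert abs(h.mobility - sinusoid_mobility(10, 200)) < 1e-3
        assert h.activity == pytest.approx(0.5, rel=1e-3)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            hjorth_parameters(np.ones(100))

    @pytest.mark.parametrize("c", [-3.0, 0.1, 7.5])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        h1 = hjorth_parameters(x)
        h2 = hjorth_parameters(c * x)
        assert h2.mobility == pytest.approx(h1.mobility, rel=1e-12)
        assert h2.complexity == pytest.approx(h1.complexity, rel=1e-12)
        assert h2.activity == pytest.approx(c ** 2 * h1.activity, rel=1e-12)

    def test_mobility_increasing_in_frequency(self):
        fs = 1000
        mobs = [hjorth_parameters(_sine(f, fs, 4)).mobility
                for f in (5, 20, 80, 200, 450)]
        assert np.all(np.diff(mobs) > 0)


class TestBandAmplitude:
    def test_in_band_vs_out_of_band_margin(self):
        x = _sine(30, 1000, 1)
        hblg = band_amplitude(x, BandDefinition("HB-LG", 20, 42), 1000)
        gamma = band_amplitude(x, BandDefinition("gamma", 60, 90), 1000)
        # log-power difference > 20 dB (= ln(100) nats)
        assert (hblg - gamma) > np.log(100)

    def test_white_noise_flat_across_bands(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200_000)
        lo = band_amplitude(x, BandDefinition("a", 20, 42), 1000)
        hi = band_amplitude(x, BandDefinition("b", 60, 90), 1000)
        assert abs(np.exp(lo - hi) - 1) < 0.2  # per-Hz power equal within 20%

    def test_zero_window_hits_floor(self):
        v = band_amplitude(np.zeros(1000), BandDefinition("a", 20, 42), 1000,
                           eps=1e-20)
        assert v == pytest.approx(np.log(1e-20))

    def test_band_outside_nyquist(self):
        with pytest.raises(ConfigurationError):
            band_amplitude(np.zeros(1000), BandDefinition("bad", 80, 120), 200)

    def test_phase_invariance(self):
        vals = [band_amplitude(_sine(30, 1000, 1, phase), BandDefinition("a", 20, 42), 1000)
                for phase in (0, 0.7, 2.1, np.pi)]
        assert np.ptp(np.exp(vals)) / np.exp(vals[0]) < 0.01


class TestBursts:
    def test_quiet_signal_zero_rate(self):
        rng = np.random.default_rng(0)
        x = 0.01 * rng.standard_normal(5000)
        rate, dur = burst_metrics(x, BandDefinition("g", 60, 90), 1000,
                                  threshold=1.0)
        assert rate == 0.0 and dur == 0.0

    def test_injected_bursts_recovered(self):
        fs = 1000
        rng = np.random.default_rng(2)
        x = 0.1 * rng.standard_normal(10 * fs)
        t = np.arange(int(0.1 * fs)) / fs
        for k in range(5):  # five 100 ms 70 Hz bursts in 10 s
            i0 = fs + k * 18 * fs // 10
            x[i0:i0 + len(t)] += 5 * np.sin(2 * np.pi * 70 * t)
        rate, dur = burst_metrics(x, BandDefinition("g", 60, 90), fs,
                                  threshold_pct=90)
        assert abs(rate - 0.5) / 0.5 < 0.2
        assert 0.05 < dur < 0.3

    def test_bad_threshold(self):
        with pytest.raises(ConfigurationError):
            burst_metrics(np.zeros(1000), BandDefinition("g", 60, 90), 1000,
                          threshold_pct=0)


class TestExtraction:
    def test_window_arithmetic_and_backfill(self):
        rec = make_recording(np.random.default_rng(0).standard_normal(10_000),
                             1000.0)
        fm = extract_neural_features(rec, feature_rate=200.0, est_window=1.0)
        assert fm.n_samples == 10 * 200
        first_valid = int(np.ceil(1.0 * 200)) - 1  # n_out - valid count
        assert 10 * 200 - first_valid == 10 * 200 - np.ceil(1.0 * 200) + 1
        # back-filled rows equal the first valid row
        np.testing.assert_array_equal(fm.values[:first_valid],
                                      np.tile(fm.values[first_valid],
                                              (first_valid, 1)))

    def test_stationary_sinusoid_constant_feature(self):
        rec = make_recording(_sine(30, 1000, 10), 1000.0)
        fm = extract_neural_features(rec, feature_rate=200.0)
        col = fm.column("HB-LG amplitude ch0 (L)")
        valid = col[200:]
        assert np.ptp(np.exp(valid)) / np.exp(valid).mean() < 0.01

    def test_causal_response_to_splice(self):
        fs = 1000
        x = np.concatenate([_sine(75, fs, 5), _sine(30, fs, 5)])
        fm = extract_neural_features(make_recording(x, fs), feature_rate=200.0,
                                     est_window=1.0)
        col = fm.column("HB-LG amplitude ch0 (L)")
        t = fm.times
        before = col[(t > 3.5) & (t < 4.995)].mean()
        after = col[(t > 6.0) & (t < 7.0)].mean()  # one est_window past splice
        assert after - before > np.log(100)
        # strictly causal: nothing moves before the splice
        assert np.ptp(col[(t > 3.0) & (t < 4.99)]) < 0.5

    def test_too_short_recording(self):
        with pytest.raises(InsufficientDataError):
            extract_neural_features(make_recording(np.zeros(500), 1000.0),
                                    est_window=1.0)

    def test_hemisphere_suffixes(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((2, 4000)),
                             1000.0, ["M1L", "M1R"], ["left", "right"])
        fm = extract_neural_features(rec, feature_rate=200.0, est_window=0.5)
        assert any(n.endswith("(L)") for n in fm.names)
        assert any(n.endswith("(R)") for n in fm.names)


class TestStatePSD:
    def test_state_ordering_with_injected_band(self):
        fs = 1000
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10 * fs)
        ev = make_events([("gait", 0, 4), ("akinesia", 4, 8), ("gait", 8, 10)], 10.0)
        t = np.arange(10 * fs) / fs
        x += 3 * np.sin(2 * np.pi * 30 * t) * ((t >= 4) & (t < 8))
        summary = state_psd(make_recording(x, fs), ev)
        assert summary.band_means["akinesia"] > summary.band_means["gait"]

    def test_short_occurrence_excluded(self):
        fs = 1000
        x = np.random.default_rng(0).standard_normal(5 * fs)
        ev = make_events([("gait", 0, 1.0), ("gait", 2, 4)], 5.0)
        summary = state_psd(make_recording(x, fs), ev)
        assert summary.excluded_counts["gait"] == 1
        assert summary.occurrence_counts["gait"] == 1

    def test_welch_parseval(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(60_000)
        freqs, pxx = welch_psd(x, 1000.0)
        integral = np.trapezoid(pxx, freqs)
        assert abs(integral - x.var()) / x.var() < 0.05

    def test_order_invariance(self):
        fs = 1000
        x = np.random.default_rng(5).standard_normal(8 * fs)
        ev1 = make_events([("gait", 0, 2), ("gait", 4, 6)], 8.0)
        ev2 = make_events([("gait", 4, 6), ("gait", 0, 2)], 8.0)
        s1 = state_psd(make_recording(x, fs), ev1)
        s2 = state_psd(make_recording(x, fs), ev2)
        np.testing.assert_allclose(s1.mean_power["gait"], s2.mean_power["gait"])
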
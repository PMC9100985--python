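"""Feature families against closed forms and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from ibpforecast.features import (
    CHANGE_NAMES,
    FEATURE_NAMES,
    FOURIER_NAMES,
    PEAK_NAMES,
    STAT_NAMES,
    WAVELET_NAMES,
    FeatureConfig,
    best_mean_split,
    change_features,
    extract_all,
    fourier_features,
    peak_features,
    statistical_features,
    wavelet_features,
    wavelet_period_grid,
)

FS = 100.0


def pulse_window(offset=85.0, amp=22.5, freq=1.0, n=2000, fs=FS):
    t = np.arange(n) / fs
    return offset + amp * np.sin(2 * np.pi * freq * t)


class TestStatisticalFeatures:
    def test_constant_window_closed_forms(self):
        out = statistical_features(np.full(2000, 80.0))
        assert out["mean"] == out["max"] == out["min"] == 80.0
        assert out["sd"] == out["skewness"] == out["kurtosis"] == out["iqr"] == 0.0
        assert out["rms"] == pytest.approx(80.0)
        assert out["rss"] == pytest.approx(80.0 * np.sqrt(2000))

    def test_sinusoid_closed_forms(self):
        # whole periods: rms^2 = offset^2 + amp^2/2, skew 0, excess kurtosis -1.5
        out = statistical_features(pulse_window())
        assert out["rms"] == pytest.approx(np.sqrt(85.0**2 + 22.5**2 / 2), rel=1e-9)
        assert out["skewness"] == pytest.approx(0.0, abs=1e-9)
        assert out["kurtosis"] == pytest.approx(-1.5, abs=1e-9)

    def test_rss_convention_switch(self):
        x = pulse_window()
        std = statistical_features(x)["rss"]
        alt = statistical_features(x, rss_convention="rms_times_n")["rss"]
        assert std == pytest.approx(np.sqrt(np.sum(x**2)))
        assert alt == pytest.approx(np.sqrt(np.mean(x**2)) * x.size)

    def test_matches_two_pass_oracle(self, rng):
        for _ in range(20):
            x = rng.uniform(20, 200, size=int(rng.integers(10, 500)))
            out = statistical_features(x)
            mu = sum(x) / len(x)
            dev = x - mu
            assert out["mean"] == pytest.approx(mu, abs=1e-9)
            assert out["sd"] == pytest.approx(np.sqrt(np.sum(dev**2) / (len(x) - 1)), abs=1e-9)
            assert out["iqr"] == pytest.approx(
                np.percentile(x, 75) - np.percentile(x, 25), abs=1e-9
            )

    def test_short_window_raises(self):
        with pytest.raises(ValueError):
            statistical_features(np.ones(3))


class TestPeakFeatures:
    def test_no_subthreshold_minima(self):
        x = pulse_window(offset=85, amp=25)  # troughs at 60... wait: 60 < 65
        x = pulse_window(offset=95, amp=25)  # troughs at 70, all above 65
        out = peak_features(x, FS)
        assert out["p_n"] == 0
        assert out["p_interval"] == out["p_mean"] == 0.0
        assert out["cf"] == pytest.approx(x.max() / np.sqrt(np.mean(x**2)))

    def test_sinusoid_troughs(self):
        # 1.25 Hz, offset 60, amp 10: 25 troughs of value 50, spaced 80 samples
        x = pulse_window(offset=60, amp=10, freq=1.25)
        out = peak_features(x, FS)
        assert out["p_n"] == 25
        assert out["p_interval"] == pytest.approx(80.0)
        assert out["p_interval_std"] == pytest.approx(0.0, abs=1e-9)
        assert out["p_mean"] == pytest.approx(50.0, abs=1e-6)
        assert out["p_std"] == pytest.approx(0.0, abs=1e-6)

    def test_two_trough_hand_enumeration(self):
        x = np.full(300, 70.0)
        for idx, val in ((100, 60.0), (180, 58.0)):
            x[idx - 5 : idx + 6] = np.linspace(70, val, 6).tolist() + np.linspace(
                val, 70, 6
            )[1:].tolist()
        out = peak_features(x, FS)
        assert out["p_n"] == 2
        assert out["p_interval"] == pytest.approx(80.0)
        assert out["p_interval_std"] == 0.0
        assert out["p_mean"] == pytest.approx(59.0)
        assert out["p_max"] == pytest.approx(60.0)
        assert out["p_min"] == pytest.approx(58.0)

    def test_matches_brute_force_minima_scan(self, rng):
        # troughs below threshold, isolated by > spacing: brute-force count
        x = np.full(2000, 80.0)
        positions = np.arange(100, 1900, 150)
        vals = rng.uniform(40, 64, size=positions.size)
        for p, v in zip(positions, vals):
            x[p - 3 : p + 4] = [70, 66, v + 2, v, v + 2, 66, 70]
        out = peak_features(x, FS)
        assert out["p_n"] == positions.size
        assert out["p_min"] == pytest.approx(vals.min())


class TestChangeFeatures:
    def test_constant_window_no_changes(self):
        out = change_features(np.full(500, 80.0))
        assert out == {"cp1": 0.0, "cp2": 0.0, "cp3": 0.0}

    def test_step_in_mean_detected_at_location(self, rng):
        x = np.concatenate([np.full(1000, 70.0), np.full(1000, 90.0)])
        x = x + rng.normal(0, 1.0, size=2000)
        out = change_features(x)
        assert out["cp1"] == 1.0
        assert abs(best_mean_split(x) - 1000) <= 10

    def test_variance_step_detected(self, rng):
        x = np.concatenate([rng.normal(80, 1, 1000), rng.normal(80, 8, 1000)])
        out = change_features(x)
        assert out["cp2"] == 1.0

    def test_indicators_are_binary(self, rng):
        for _ in range(10):
            x = rng.uniform(60, 110, size=256)
            out = change_features(x)
            assert set(out.values()) <= {0.0, 1.0}

    def test_mean_split_matches_exhaustive_oracle(self, rng):
        # naive per-split SSE loop = the stated cost definition
        for _ in range(10):
            x = rng.normal(80, 5, size=int(rng.integers(64, 300)))
            x[len(x) // 2 :] += rng.uniform(-10, 10)
            best, best_k = np.inf, None
            for k in range(8, len(x) - 8 + 1):
                sse = np.sum((x[:k] - x[:k].mean()) ** 2) + np.sum(
                    (x[k:] - x[k:].mean()) ** 2
                )
                if sse < best:
                    best, best_k = sse, k
            assert best_mean_split(x) == best_k


class TestFourierFeatures:
    def test_single_tone_frequency_within_one_bin(self):
        x = pulse_window(offset=85, amp=20, freq=1.3)
        out = fourier_features(x, FS)
        assert out["freq1"] == pytest.approx(1.3, abs=0.05)
        assert out["po1"] >= out["po2"] >= out["po3"] >= 0

    def test_constant_window_zero_power_lowest_bins(self):
        out = fourier_features(np.full(2000, 80.0), FS)
        assert out["po1"] == out["po2"] == out["po3"] == 0.0
        assert [out["freq1"], out["freq2"], out["freq3"]] == pytest.approx(
            [0.05, 0.10, 0.15]
        )

    def test_two_tone_power_ordering(self):
        t = np.arange(2000) / FS
        x = 85 + 20 * np.sin(2 * np.pi * 1.0 * t) + 5 * np.sin(2 * np.pi * 2.0 * t)
        out = fourier_features(x, FS)
        assert out["freq1"] == pytest.approx(1.0, abs=0.05)


class TestWaveletFeatures:
    @pytest.mark.parametrize("period", [0.787, 2.0])
    def test_pure_tone_pseudo_period_calibration(self, period):
        t = np.arange(2000) / FS
        x = 85 + 20 * np.sin(2 * np.pi * t / period)
        out = wavelet_features(x, FS)
        grid = wavelet_period_grid()
        step = grid[1] / grid[0]
        assert out["scale1"] == pytest.approx(period, abs=period * (step - 1))

    def test_constant_window_degenerate(self):
        out = wavelet_features(np.full(2000, 80.0), FS)
        grid = wavelet_period_grid()
        assert [out[f"scale{i}"] for i in range(1, 11)] == list(grid[:10])


class TestExtractAll:
    def test_exactly_36_named_features_in_family_order(self):
        out = extract_all(pulse_window(), FS)
        assert tuple(out) == FEATURE_NAMES
        assert len(out) == 36
        assert all(np.isfinite(v) for v in out.values())
        assert (len(STAT_NAMES), len(PEAK_NAMES) + len(CHANGE_NAMES)) == (9, 11)
        assert (len(FOURIER_NAMES), len(WAVELET_NAMES)) == (6, 10)

    def test_deterministic(self):
        x = pulse_window(offset=70, amp=15, freq=1.27)
        assert extract_all(x, FS) == extract_all(x, FS)

    def test_offset_shift_equivariance(self):
        x = pulse_window(offset=60, amp=10, freq=1.25)  # troughs at 50 / 60
        a = extract_all(x, FS)
        b = extract_all(x + 10.0, FS)
        for name in ("mean", "max", "min", "p_mean", "p_max", "p_min"):
            assert b[name] - a[name] == pytest.approx(10.0, abs=1e-6)
        for name in ("sd", "iqr", "skewness", "kurtosis", "p_n", "p_interval",
                     "freq1", "freq2", "freq3", "po1", "cp1", "cp2", "cp3",
                     "scale1", "scale2"):
            assert b[name] == pytest.approx(a[name], abs=1e-6)

    def test_spectral_wavelet_consistency(self):
        x = pulse_window(offset=85, amp=20, freq=1.25)
        out = extract_all(x, FS)
        assert out["freq1"] == pytest.approx(1.0 / out["scale1"], rel=0.08)
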
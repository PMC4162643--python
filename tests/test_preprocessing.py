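"""Preprocessing: R peaks, tachogram, resampling, detrending, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import physync as ps
from physync.preprocessing import UniformSeries


class TestRPeakDetection:
    def test_metronomic_ecg_spacing(self):
        peaks = np.arange(0.5, 29.5, 1.0)
        ecg = ps.synth_ecg(peaks, 400, 30, noise_sd=0.005)
        idx = ps.detect_r_peaks(ecg, 400)
        assert len(idx) == len(peaks)
        assert np.all(np.diff(idx) == 400)

    def test_recovers_ground_truth_within_one_sample(self):
        peaks, _rr = ps.synth_rr_sequence(0.8, 0.05, 0.25, 0.02, 120, seed=7)
        ecg = ps.synth_ecg(peaks, 400, 120, seed=1)
        idx = ps.detect_r_peaks(ecg, 400)
        true_idx = np.round(peaks * 400).astype(int)
        assert len(idx) == len(true_idx)  # zero false positives / negatives
        assert np.abs(idx - true_idx).max() <= 1

    def test_flat_trace_returns_empty_with_warning(self):
        with pytest.warns(UserWarning):
            idx = ps.detect_r_peaks(np.zeros(2000), 400)
        assert idx.size == 0

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            ps.detect_r_peaks(np.zeros(400), 50)


class TestHeartPeriodSeries:
    def test_constant_rr(self):
        peaks = np.arange(0, 20.1, 0.8)
        s = ps.build_heart_period_series(peaks)
        assert s.fs == 4.0
        assert np.allclose(s.values, 800.0, atol=1e-9)

    def test_matches_piecewise_linear_oracle(self):
        # RR rising linearly 700 -> 900 ms
        rr = np.linspace(0.7, 0.9, 40)
        peaks = np.concatenate([[0.0], np.cumsum(rr)])
        s = ps.build_heart_period_series(peaks)
        # independent oracle: direct linear interpolation at the grid times
        expected = np.interp(s.times, peaks[1:], rr * 1000)
        assert np.allclose(s.values, expected, atol=1e-9)
        assert s.start_time == pytest.approx(peaks[1])

    def test_two_peaks_rejected(self):
        with pytest.raises(ValueError):
            ps.build_heart_period_series([0.0, 0.8])


class TestResampling:
    def test_constant_preserved(self):
        out = ps.resample_to_4hz(np.full(400 * 60, 5.0), 400)
        assert len(out.values) == 240
        assert np.abs(out.values - 5.0).max() < 1e-6

    def test_sinusoid_matches_analytic(self):
        t = np.arange(400 * 60) / 400
        out = ps.resample_to_4hz(np.sin(2 * np.pi * 0.2 * t), 400)
        ref = np.sin(2 * np.pi * 0.2 * out.times)
        interior = slice(8, -8)  # 2 s margin at each edge
        assert np.abs(out.values - ref)[interior].max() < 1e-3

    def test_passband_edge_and_alias_suppression(self):
        t = np.arange(400 * 60) / 400
        near = ps.resample_to_4hz(np.sin(2 * np.pi * 1.9 * t), 400)
        amp = np.percentile(np.abs(near.values[8:-8]), 99.9)
        assert amp > 0.95  # 1.9 Hz preserved within 5%
        above = ps.resample_to_4hz(np.sin(2 * np.pi * 2.5 * t), 400)
        assert np.var(above.values[8:-8]) / 0.5 < 0.01  # aliasing suppressed

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(4000), rng.standard_normal(4000)
        lhs = ps.resample_to_4hz(2.0 * a + 3.0 * b, 40).values
        rhs = 2.0 * ps.resample_to_4hz(a, 40).values + 3.0 * ps.resample_to_4hz(b, 40).values
        assert np.abs(lhs - rhs).max() < 1e-9

    def test_subnyquist_input_rejected(self):
        with pytest.raises(ValueError):
            ps.resample_to_4hz(np.zeros(100), 2.0)


class TestDetrend:
    def test_removes_exact_line(self):
        t = np.arange(100, dtype=float)
        s = UniformSeries(3.0 + 0.5 * t, fs=4.0)
        out = ps.linear_detrend(s)
        assert np.abs(out.values).max() < 1e-10

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_and_orthogonal_and_contractive(self, seed):
        rng = np.random.default_rng(seed)
        x = UniformSeries(rng.standard_normal(64), fs=4.0)
        once = ps.linear_detrend(x)
        twice = ps.linear_detrend(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)
        n = len(once.values)
        const = np.ones(n) / np.sqrt(n)
        lin = np.arange(n) - (n - 1) / 2
        lin = lin / np.linalg.norm(lin)
        assert abs(once.values @ const) < 1e-8 * max(1, np.abs(once.values).max())
        assert abs(once.values @ lin) < 1e-8 * max(1, np.abs(once.values).max())
        assert once.values.var() <= x.values.var() + 1e-12

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ps.linear_detrend(UniformSeries([1.0], fs=4.0))


class TestAssembly:
    def test_aligned_series_shape(self):
        series = [UniformSeries(np.random.default_rng(i).standard_normal(480), 4.0)
                  for i in range(10)]
        mat = ps.assemble_group_matrix(series, [f"S{i}" for i in range(10)], "accel")
        assert mat.values.shape == (10, 480)
        assert mat.detrended
        # detrended rows: zero linear fit
        for row in mat.values:
            fit = np.polyfit(np.arange(len(row)), row, 1)
            assert np.abs(fit).max() < 1e-9 * max(1.0, np.abs(row).max())

    def test_truncates_to_common_support(self):
        a = UniformSeries(np.zeros(480), 4.0, start_time=0.0)
        b = UniformSeries(np.zeros(476), 4.0, start_time=1.0)
        mat = ps.assemble_group_matrix([a, b], ["a", "b"], "accel")
        assert mat.values.shape[1] <= 476

    def test_mixed_rates_rejected(self):
        a = UniformSeries(np.zeros(40), 4.0)
        b = UniformSeries(np.zeros(80), 8.0)
        with pytest.raises(ValueError):
            ps.assemble_group_matrix([a, b], ["a", "b"], "accel")


class TestEndToEnd:
    def test_tachogram_recovery_correlation(self, small_session):
        # clean-signal regime: recovered 4 Hz heart period tracks the truth
        rec = small_session[0]
        idx = ps.detect_r_peaks(rec.channels["ecg"], rec.fs)
        series = ps.build_heart_period_series(idx / rec.fs)
        truth = rec.ground_truth
        true_rr_ms = truth["rr_intervals"] * 1000
        expected = np.interp(series.times, truth["r_peak_times"][1:], true_rr_ms)
        r = np.corrcoef(series.values, expected)[0, 1]
        assert r > 0.99

    def test_preprocess_condition_shapes(self, small_session):
        mats = ps.preprocess_condition(small_session)
        assert set(mats) == {"ecg", "resp_abd", "resp_thor", "accel"}
        for mat in mats.values():
            assert mat.fs == 4.0
            assert mat.n_subjects == 4
            assert mat.n_samples >= 460  # ~120 s at 4 Hz, minus tachogram edges
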
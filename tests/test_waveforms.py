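"""Waveform container, CSV round trips, normalization and averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from windkessel3.waveforms import (GRID, NormalizedWaveform, Waveform,
                                   WaveformError, average_waveforms,
                                   normalize_waveform, read_waveform,
                                   smooth_pressure_trace, waveform_mean,
                                   write_waveform)


def fourier_waveform(coeffs, period=1.0, n=128, mean=10.0, quantity="flow"):
    t = np.arange(n) / n * period
    v = np.full(n, mean)
    for k, (a, b) in enumerate(coeffs, start=1):
        v += a * np.cos(2 * np.pi * k * t / period) + b * np.sin(2 * np.pi * k * t / period)
    return Waveform(time=t, value=v, period=period, quantity=quantity)


class TestWaveformInvariants:
    def test_rejects_non_monotone_time(self):
        with pytest.raises(WaveformError, match="monotone"):
            Waveform(time=[0.0, 0.5, 0.2], value=[1, 1, 1], period=1.0, quantity="flow")

    def test_rejects_nonfinite_values(self):
        with pytest.raises(WaveformError, match="finite"):
            Waveform(time=[0, 0.1, 0.2], value=[1, np.nan, 1], period=1.0, quantity="flow")

    def test_rejects_nonpositive_pressure(self):
        with pytest.raises(WaveformError, match="positive"):
            Waveform(time=[0, 0.1, 0.2], value=[80, -1, 80], period=1.0, quantity="pressure")

    def test_flow_reversal_allowed(self):
        w = Waveform(time=[0, 0.1, 0.2], value=[5, -2, 5], period=1.0, quantity="flow")
        assert w.value.min() < 0

    def test_rejects_full_period_span(self):
        t = np.linspace(0, 1.0, 11)
        with pytest.raises(WaveformError, match="full period"):
            Waveform(time=t, value=np.ones(11), period=1.0, quantity="flow")


class TestCsvRoundTrip:
    def test_reads_constant_flow(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("# quantity=flow units=mL/s period_s=1\ntime_s,value\n0,5\n0.5,5\n")
        w = read_waveform(path)
        assert w.quantity == "flow" and w.period == 1.0
        np.testing.assert_allclose(w.value, 5.0)

    def test_converts_ml_per_min(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("# quantity=flow units=mL/min period_s=1\ntime_s,value\n0,5\n0.5,5\n")
        w = read_waveform(path)
        np.testing.assert_allclose(w.value, 5.0 / 60.0)

    def test_non_monotone_time_errors(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("# quantity=flow units=mL/s period_s=1\ntime_s,value\n0.5,1\n0.2,1\n")
        with pytest.raises(WaveformError, match="non-monotone"):
            read_waveform(path)

    def test_missing_period_errors(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("# quantity=flow units=mL/s\ntime_s,value\n0,1\n0.5,1\n")
        with pytest.raises(WaveformError, match="period"):
            read_waveform(path)

    def test_nan_value_errors(self, tmp_path):
        path = tmp_path / "w.csv"
        path.write_text("# quantity=flow units=mL/s period_s=1\ntime_s,value\n0,1\n0.5,nan\n")
        with pytest.raises(WaveformError, match="NaN"):
            read_waveform(path)

    def test_write_read_round_trip(self, tmp_path, carotid_flow):
        path = tmp_path / "w.csv"
        write_waveform(carotid_flow, path)
        back = read_waveform(path)
        assert back.period == pytest.approx(carotid_flow.period, rel=1e-8)
        np.testing.assert_allclose(back.value, carotid_flow.value, rtol=1e-5)
        np.testing.assert_allclose(back.time, carotid_flow.time, rtol=1e-5, atol=1e-9)


class TestWaveformMean:
    def test_constant(self):
        w = Waveform(time=np.arange(20) / 20, value=np.full(20, 7.63),
                     period=1.0, quantity="flow")
        assert waveform_mean(w) == pytest.approx(7.63)

    def test_sinusoid_averages_out(self):
        t = np.arange(256) / 256
        w = Waveform(time=t, value=80 + 20 * np.sin(2 * np.pi * t),
                     period=1.0, quantity="pressure")
        assert waveform_mean(w) == pytest.approx(80.0, abs=1e-6)

    def test_triangular_pulse_matches_fine_quadrature(self):
        # nodes of the triangle coincide with samples -> trapezoid is exact,
        # and so is dense linear-interpolation quadrature (the oracle)
        t = np.array([0.0, 0.2, 0.4, 0.6, 0.8])
        v = np.array([0.0, 5.0, 0.0, 0.0, 0.0])
        w = Waveform(time=t, value=v, period=1.0, quantity="flow")
        tf = np.linspace(0, 1, 100001)
        vf = np.interp(np.mod(tf, 1.0), np.append(t, 1.0), np.append(v, v[0]))
        oracle = np.trapezoid(vf, tf)
        assert waveform_mean(w) == pytest.approx(oracle, abs=1e-6)


class TestNormalize:
    def test_constant_pressure_maps_to_one(self):
        w = Waveform(time=np.arange(20) / 20, value=np.full(20, 85.0),
                     period=1.0, quantity="pressure")
        n = normalize_waveform(w)
        np.testing.assert_allclose(n.value, 1.0, atol=1e-12)

    def test_sinusoid_amplitude_and_mean(self):
        t = np.arange(256) / 256 * 0.8
        w = Waveform(time=t, value=80 + 20 * np.sin(2 * np.pi * t / 0.8),
                     period=0.8, quantity="pressure")
        n = normalize_waveform(w)
        assert n.value.mean() == pytest.approx(1.0, abs=1e-9)
        assert (n.value.max() - 1.0) == pytest.approx(0.25, abs=1e-4)

    def test_zero_mean_flow_errors(self):
        t = np.arange(64) / 64
        w = Waveform(time=t, value=np.sin(2 * np.pi * t), period=1.0, quantity="flow")
        with pytest.raises(WaveformError, match="zero"):
            normalize_waveform(w)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(-2, 2)), min_size=0, max_size=5),
           st.floats(0.5, 2.0), st.floats(5.0, 50.0))
    def test_idempotent_with_unit_mean(self, coeffs, period, mean):
        w = fourier_waveform(coeffs, period=period, mean=mean)
        n1 = normalize_waveform(w)
        assert abs(waveform_mean(
            Waveform(time=GRID, value=n1.value, period=1.0, quantity="flow")) - 1.0) < 1e-6
        n2 = normalize_waveform(
            Waveform(time=GRID, value=n1.value, period=1.0, quantity="flow"))
        np.testing.assert_allclose(n2.value, n1.value, atol=1e-9)


class TestAverage:
    def test_identical_members_zero_sd(self):
        m = NormalizedWaveform(value=1 + 0.1 * np.sin(2 * np.pi * GRID)
                               - (0.1 * np.sin(2 * np.pi * GRID)).mean(),
                               quantity="flow")
        ens = average_waveforms([m, m])
        np.testing.assert_allclose(ens.pointwise_mean.value, m.value, atol=1e-12)
        np.testing.assert_allclose(ens.pointwise_sd, 0.0, atol=1e-15)

    def test_symmetric_members_cancel(self):
        s = 0.1 * np.sin(2 * np.pi * GRID)
        s -= s.mean()
        a = NormalizedWaveform(value=1 + s, quantity="pressure")
        b = NormalizedWaveform(value=1 - s, quantity="pressure")
        ens = average_waveforms([a, b])
        np.testing.assert_allclose(ens.pointwise_mean.value, 1.0, atol=1e-12)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(7)
        members = []
        for _ in range(10):
            v = 1 + 0.2 * rng.standard_normal(GRID.size)
            members.append(NormalizedWaveform(value=v / v.mean(), quantity="flow"))
        ens = average_waveforms(members)
        brute = np.stack([m.value for m in members]).mean(axis=0)
        np.testing.assert_allclose(ens.pointwise_mean.value, brute, rtol=1e-12)

    def test_empty_and_mixed_quantities_error(self):
        with pytest.raises(WaveformError, match="empty"):
            average_waveforms([])
        f = NormalizedWaveform(value=np.ones(100), quantity="flow")
        p = NormalizedWaveform(value=np.ones(100), quantity="pressure")
        with pytest.raises(WaveformError, match="mixed"):
            average_waveforms([f, p])


class TestSmoothing:
    @staticmethod
    def _recording(duration=2.0, n=2000, noise_sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n) / n * duration
        v = 90 + 15 * np.sin(2 * np.pi * t) + 5 * np.sin(4 * np.pi * t + 0.7)
        v = v + noise_sd * rng.standard_normal(n)
        return Waveform(time=t, value=v, period=duration, quantity="pressure")

    def test_period_from_heart_rate(self):
        out = smooth_pressure_trace(self._recording(), heart_rate=60)
        assert out.period == pytest.approx(1.0)

    def test_noiseless_trace_preserved(self):
        raw = self._recording()
        out = smooth_pressure_trace(raw, heart_rate=60)
        expect = 90 + 15 * np.sin(2 * np.pi * out.time) + 5 * np.sin(4 * np.pi * out.time + 0.7)
        np.testing.assert_allclose(out.value, expect, atol=0.05)

    def test_noisy_mean_preserved(self):
        out = smooth_pressure_trace(self._recording(noise_sd=3.0, seed=3), heart_rate=60)
        assert waveform_mean(out) == pytest.approx(90.0, rel=0.005)

    def test_short_recording_errors(self):
        raw = self._recording(duration=0.5, n=600)
        with pytest.raises(WaveformError, match="shorter than one"):
            smooth_pressure_trace(raw, heart_rate=60)
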
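import math

import numpy as np
import pytest

from owsmap.altmetrics import (
    apd80,
    delta_apd80_map,
    df_map,
    dominant_frequency,
    mean_delta_apd80,
)
from owsmap.preprocess import tissue_signal
from owsmap.segmentation import WindowSpec, detect_peaks, segment_by_pcl
from owsmap.stackio import ImageStack, Trace, ValidationError
from owsmap.synthetic import ModelSpec, make_movie, simulate_ap_train

from .conftest import stack_from_trace


def triangle_beat(rate=1000.0, rise_ms=10.0, fall_ms=100.0, lead_ms=20.0, tail_ms=40.0):
    """Sampled triangular OAP, baseline 0, peak 1; returns (values, times)."""
    dt = 1000.0 / rate
    t = np.arange(0.0, lead_ms + rise_ms + fall_ms + tail_ms, dt)
    t_peak = lead_ms + rise_ms
    v = np.where(
        t < lead_ms,
        0.0,
        np.where(
            t <= t_peak,
            (t - lead_ms) / rise_ms,
            np.maximum(1.0 - (t - t_peak) / fall_ms, 0.0),
        ),
    )
    return v, t, t_peak


class TestAPD80:
    def test_triangle_closed_form(self):
        v, t, t_peak = triangle_beat()
        apd, act = apd80(v, t)
        # analytic: the falling limb crosses the 20% level exactly at
        # t_peak + 0.8 * fall = 110 ms; activation lies on the rising limb
        # (its uniform slope makes the steepest-pair choice tie-dependent)
        assert 20.0 <= act <= t_peak
        assert act + apd == pytest.approx(t_peak + 0.8 * 100.0, abs=1e-9)

    def test_time_rescaled_beat_scales_linearly(self):
        v, t, _ = triangle_beat()
        a1, act1 = apd80(v, t)
        a2, act2 = apd80(v, 2.0 * t)  # same samples on a doubled clock
        assert a2 == pytest.approx(2.0 * a1, rel=1e-12)
        assert act2 == pytest.approx(2.0 * act1, rel=1e-12)

    def test_square_pulse_never_decaying_is_excluded(self):
        t = np.arange(0.0, 100.0)
        v = np.where(t > 20, 1.0, 0.0)
        apd, _ = apd80(v, t, next_peak_time=99.0)
        assert math.isnan(apd)

    def test_repolarisation_after_next_peak_is_excluded(self):
        v, t, _ = triangle_beat()
        apd, _ = apd80(v, t, next_peak_time=50.0)  # 80% repol is at ~110 ms
        assert math.isnan(apd)

    def test_two_identical_beats_zero_delta(self):
        v, t, _ = triangle_beat(tail_ms=40.0)
        rate = 1000.0
        train = np.concatenate([v, v])
        peaks = np.array([np.argmax(v), v.size + np.argmax(v)])
        d = mean_delta_apd80(train, rate, peaks, pre_ms=20.0)
        assert d == pytest.approx(0.0, abs=1e-9)


class TestDeltaAPDMap:
    def test_template_alternation_recovered(self, gp_template_alternans):
        stack = stack_from_trace(gp_template_alternans, 3, 3)
        cat = segment_by_pcl(detect_peaks(tissue_signal(stack)))
        res = delta_apd80_map(stack, cat, WindowSpec(50.0, 150.0))
        finite = res.alternans_map[np.isfinite(res.alternans_map)]
        assert finite.size == 9
        # generator truth: odd-beat APD = 250/1.7, even 250 ms; the sigmoid
        # repolarisation keeps the realised APD80 difference near the APD step
        expected = res.delta_apd80[0]
        expected = expected[np.isfinite(expected)]
        assert np.ptp(finite) < 1e-9  # all pixels identical by construction
        assert finite[0] == pytest.approx(np.mean(expected), abs=1e-9)
        assert 60.0 < finite[0] < 140.0

    def test_regular_train_zero_map(self, gp_template_train):
        stack = stack_from_trace(gp_template_train, 2, 2)
        cat = segment_by_pcl(detect_peaks(tissue_signal(stack)))
        res = delta_apd80_map(stack, cat, WindowSpec(50.0, 150.0))
        finite = res.alternans_map[np.isfinite(res.alternans_map)]
        np.testing.assert_allclose(finite, 0.0, atol=0.5)

    def test_delta_symmetric_under_beat_reversal(self, gp_template_alternans):
        stack = stack_from_trace(gp_template_alternans, 2, 2)
        cat = segment_by_pcl(detect_peaks(tissue_signal(stack)))
        res = delta_apd80_map(stack, cat, WindowSpec(50.0, 150.0))
        d = res.delta_apd80[np.isfinite(res.delta_apd80)]
        assert np.all(d >= 0)


class TestDominantFrequency:
    def test_pure_sinusoid(self):
        rate = 500.0
        t = np.arange(int(2 * rate)) / rate
        tr = Trace(values=np.sin(2 * np.pi * 10.0 * t), sampling_rate=rate)
        assert dominant_frequency(tr) == pytest.approx(10.0, abs=0.05)

    def test_larger_line_wins(self):
        rate = 500.0
        t = np.arange(int(4 * rate)) / rate
        v = 1.0 * np.sin(2 * np.pi * 6 * t) + 2.0 * np.sin(2 * np.pi * 14 * t)
        tr = Trace(values=v, sampling_rate=rate)
        # oracle: direct spectrum of the same windowed signal
        w = np.hanning(v.size)
        spec = np.abs(np.fft.rfft((v - v.mean()) * w, n=2 ** 14))
        freqs = np.fft.rfftfreq(2 ** 14, 1 / rate)
        sel = (freqs >= 0.5) & (freqs <= 50)
        oracle = freqs[sel][np.argmax(spec[sel])]
        assert dominant_frequency(tr) == pytest.approx(oracle, abs=0.05)
        assert dominant_frequency(tr) == pytest.approx(14.0, abs=0.05)

    def test_out_of_band_line_excluded(self):
        rate = 100.0
        t = np.arange(int(20 * rate)) / rate
        v = 5.0 * np.sin(2 * np.pi * 0.2 * t) + 0.5 * np.sin(2 * np.pi * 3.0 * t)
        tr = Trace(values=v, sampling_rate=rate)
        assert dominant_frequency(tr) == pytest.approx(3.0, abs=0.05)

    def test_band_above_nyquist_rejected(self):
        tr = Trace(values=np.sin(np.arange(100.0)), sampling_rate=40.0)
        with pytest.raises(ValidationError, match="Nyquist"):
            dominant_frequency(tr, band=(0.5, 50.0))

    @pytest.mark.parametrize("pcl_ms", [100.0, 170.0, 400.0])
    def test_pulse_train_frequency_is_inverse_pcl(self, pcl_ms):
        rate = 500.0
        n = int(10 * pcl_ms * rate / 1000.0)
        t = np.arange(n) * (1000.0 / rate)
        v = np.zeros(n)
        for k in range(10):
            v += np.exp(-0.5 * ((t - k * pcl_ms - 30.0) / 8.0) ** 2)
        f = dominant_frequency(Trace(values=v, sampling_rate=rate))
        assert f == pytest.approx(1000.0 / pcl_ms, abs=0.06)


class TestDFMap:
    def _sin_train(self, f, rate=500.0, seconds=2.0):
        t = np.arange(int(seconds * rate)) / rate
        return Trace(values=np.sin(2 * np.pi * f * t) + 1.0, sampling_rate=rate)

    def test_uniform_movie_uniform_map(self):
        stack, _ = make_movie(4, 4, self._sin_train(8.0), conduction_velocity=1e9)
        res = df_map(stack)
        np.testing.assert_allclose(res.df_map, 8.0, atol=0.05)

    def test_two_region_map_boundary(self):
        region = np.zeros((4, 6), dtype=int)
        region[:, 3:] = 1
        stack, _ = make_movie(
            4, 6, self._sin_train(6.0), conduction_velocity=1e9,
            region_map=region, region_trains={1: self._sin_train(9.0)},
        )
        res = df_map(stack)
        np.testing.assert_allclose(res.df_map[:, :3], 6.0, atol=0.05)
        np.testing.assert_allclose(res.df_map[:, 3:], 9.0, atol=0.05)

    def test_map_mean_equals_per_pixel_recompute(self):
        stack, _ = make_movie(3, 3, self._sin_train(8.0), conduction_velocity=2.0)
        res = df_map(stack)
        vals = [
            dominant_frequency(Trace(values=stack.frames[:, r, c], sampling_rate=500.0))
            for r in range(3)
            for c in range(3)
        ]
        assert res.mean_df == pytest.approx(np.mean(vals), abs=1e-9)

    def test_frequency_resolution_bound(self):
        res = df_map(make_movie(2, 2, self._sin_train(8.0), 1e9)[0])
        assert res.freq_resolution <= 0.05
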
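import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from owsmap.preprocess import tissue_signal
from owsmap.segmentation import WindowSpec, detect_peaks, segment_by_pcl
from owsmap.similarity import (
    closest_minima,
    map_over_pixels,
    ows,
    pair_trim_bounds,
    regularity_index,
    ri_threshold_sweep,
    similarity_matrix,
    single_beat_ows,
    wave_similarity,
)
from owsmap.stackio import ValidationError


def _pair_with_cosine(c: float, k: int = 16):
    """Two zero-mean unit-norm vectors with exact cosine similarity c."""
    u = np.zeros(k)
    u[: k // 2] = 1.0
    u[k // 2 :] = -1.0
    u /= np.linalg.norm(u)
    w = np.zeros(k)
    w[0], w[1] = 1.0, -1.0
    w -= w.mean()
    w -= (w @ u) * u
    w /= np.linalg.norm(w)
    return u, c * u + math.sqrt(1 - c * c) * w


def brute_force_ows(beats):
    """Independent oracle: explicit double loop over unordered pairs."""
    m = beats.shape[0]
    total = 0.0
    for i in range(m):
        for j in range(i + 1, m):
            a = beats[i] - beats[i].mean()
            b = beats[j] - beats[j].mean()
            total += (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return 2.0 * total / (m * (m - 1))


def brute_force_ri(beats, eps):
    m = beats.shape[0]
    count = 0
    for i in range(m):
        for j in range(i + 1, m):
            a = beats[i] - beats[i].mean()
            b = beats[j] - beats[j].mean()
            s = np.clip((a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)), -1, 1)
            if math.acos(s) <= eps:
                count += 1
    return 2.0 * count / (m * (m - 1))


class TestWaveSimilarity:
    def test_identical_vectors_give_one(self, rng):
        a = rng.random(32)
        assert wave_similarity(a, a.copy()) == pytest.approx(1.0, abs=1e-12)

    def test_opposite_phase_gives_minus_one(self, rng):
        a = rng.random(32)
        assert wave_similarity(a, -a) == pytest.approx(-1.0, abs=1e-12)

    def test_orthogonal_zero_mean_vectors_give_zero(self):
        a = np.array([1.0, 0.0, -1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, -1.0])
        assert wave_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_constant_vector_yields_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert wave_similarity(np.ones(8), np.arange(8.0)) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            wave_similarity(np.ones(4), np.ones(5))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        alpha=st.floats(0.01, 100.0),
        beta=st.floats(-50.0, 50.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, alpha, beta, seed):
        r = np.random.default_rng(seed)
        a, b = r.random(24), r.random(24)
        s0 = wave_similarity(a, b)
        s1 = wave_similarity(alpha * a + beta, b)
        assert s1 == pytest.approx(s0, abs=1e-9)


class TestOWS:
    def test_identical_train_gives_one(self, rng):
        beat = rng.random(40)
        beats = np.tile(beat, (6, 1))
        assert ows(beats) == pytest.approx(1.0, abs=1e-12)

    def test_alternating_train_closed_form(self):
        # A,B,A,B with s(A,B)=c -> OWS = (1 + 2c) / 3
        a, b = _pair_with_cosine(0.5)
        beats = np.stack([a, b, a, b])
        assert ows(beats) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_matches_bruteforce_loop(self, rng):
        beats = rng.random((5, 30))
        assert ows(beats) == pytest.approx(brute_force_ows(beats), abs=1e-12)

    def test_equals_upper_triangle_mean_of_similarity_matrix(self, rng):
        for m in (2, 3, 8):
            beats = rng.random((m, 20))
            sm = similarity_matrix(beats)
            iu = np.triu_indices(m, k=1)
            assert ows(beats) == pytest.approx(sm.s[iu].mean(), abs=1e-12)

    def test_single_beat_undefined_warns_nan(self):
        with pytest.warns(UserWarning):
            assert math.isnan(ows(np.random.default_rng(0).random((1, 10))))

    def test_similarity_matrix_invariants(self, rng):
        beats = rng.random((6, 25))
        sm = similarity_matrix(beats)
        np.testing.assert_allclose(sm.s, sm.s.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sm.s), 1.0, atol=1e-9)
        assert np.all(sm.s >= -1 - 1e-9) and np.all(sm.s <= 1 + 1e-9)


class TestSingleBeatOWS:
    def test_identical_train_all_ones(self, rng):
        beats = np.tile(rng.random(30), (5, 1))
        np.testing.assert_allclose(single_beat_ows(beats), 1.0, atol=1e-12)

    def test_strict_alternation_constant_series(self):
        a, b = _pair_with_cosine(0.3)
        series = single_beat_ows(np.stack([a, b, a, b, a]))
        np.testing.assert_allclose(series, 0.3, atol=1e-12)

    def test_one_aberrant_beat_dips_twice(self, rng):
        base = rng.random(30)
        beats = np.tile(base, (6, 1))
        beats[3] = rng.random(30)
        series = single_beat_ows(beats)
        dips = np.nonzero(series < 0.999)[0]
        np.testing.assert_array_equal(dips, [2, 3])


class TestRegularityIndex:
    def test_identical_train_is_one_at_any_epsilon(self, rng):
        beats = np.tile(rng.random(30), (5, 1))
        for eps in (0.0, 0.01, math.pi / 6, math.pi):
            assert regularity_index(beats, eps) == pytest.approx(1.0)

    def test_alternating_pairs_counted_exactly(self):
        # d(A,B) = pi/3, epsilon = pi/6, M=4 -> only the 2 same-parity pairs
        a, b = _pair_with_cosine(math.cos(math.pi / 3))
        beats = np.stack([a, b, a, b])
        assert regularity_index(beats, math.pi / 6) == pytest.approx(1.0 / 3.0)

    def test_epsilon_pi_is_one_for_any_data(self, rng):
        assert regularity_index(rng.random((6, 20)), math.pi) == 1.0

    def test_boundary_pair_counts_as_similar(self):
        a, b = _pair_with_cosine(math.cos(math.pi / 4))
        beats = np.stack([a, b])
        assert regularity_index(beats, math.pi / 4 + 1e-12) == 1.0

    def test_epsilon_out_of_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            regularity_index(rng.random((3, 10)), -0.1)

    def test_sweep_matches_enumeration_and_monotone(self):
        a, b = _pair_with_cosine(math.cos(math.pi / 4))
        beats = np.stack([a, b, a, b])
        out = ri_threshold_sweep(beats, [math.pi / 18, math.pi / 6, math.pi / 3])
        np.testing.assert_allclose(out, [1 / 3, 1 / 3, 1.0], atol=1e-12)
        assert np.all(np.diff(out) >= 0)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 500), m=st.integers(2, 8))
    def test_sweep_monotone_property(self, seed, m):
        beats = np.random.default_rng(seed).random((m, 16))
        eps = np.linspace(0, math.pi, 12)
        assert np.all(np.diff(ri_threshold_sweep(beats, eps)) >= -1e-12)


class TestMinimaTrimming:
    def test_trim_bounds_match_hand_computed_minima(self):
        # triangular OAPs with known minima: peak at index 6
        a = np.array([3.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 8.0, 6.0, 4.0, 2.0, 3.0, 5.0])
        b = np.array([5.0, 4.0, 2.5, 4.0, 6.0, 8.0, 9.0, 7.0, 5.0, 3.0, 3.5, 3.0, 4.0])
        assert closest_minima(a, 6) == (1, 10)
        assert closest_minima(b, 6) == (2, 9)
        # closest of either: pre = max(1, 2) = 2, post = min(10, 9) = 9
        assert pair_trim_bounds(a, b, 6) == (2, 9)

    def test_monotone_sides_fall_back_to_window_edges(self):
        v = np.array([0.0, 1.0, 2.0, 5.0, 2.0, 1.0, 0.5])
        assert closest_minima(v, 3) == (0, 6)

    def test_trimmed_similarity_uses_shared_window(self):
        a = np.array([3.0, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 8.0, 6.0, 4.0, 2.0, 3.0, 5.0])
        b = np.array([5.0, 4.0, 2.5, 4.0, 6.0, 8.0, 9.0, 7.0, 5.0, 3.0, 3.5, 3.0, 4.0])
        expected = wave_similarity(a[2:10], b[2:10])
        assert wave_similarity(a, b, trim=True, peak=6) == pytest.approx(expected)


class TestMaps:
    def test_uniform_movie_maps_to_one(self, uniform_movie):
        stack, _ = uniform_movie
        cat = segment_by_pcl(detect_peaks(tissue_signal(stack)))
        res = map_over_pixels(stack, cat, WindowSpec(50.0, 150.0), metric="ows")
        finite = res.ows_map[np.isfinite(res.ows_map)]
        assert finite.size == stack.mask.sum()
        assert np.all(finite > 0.99)

    def test_two_region_alternans_boundary_recovered(self, two_region_movie):
        stack, truth = two_region_movie
        cat = segment_by_pcl(detect_peaks(tissue_signal(stack)))
        res = map_over_pixels(stack, cat, WindowSpec(50.0, 150.0), metric="ows")
        left = np.nanmean(res.ows_map[:, :5])
        right = np.nanmean(res.ows_map[:, 5:])
        assert left < right - 0.01
        # boundary within one pixel of construction: classify by midpoint
        mid = 0.5 * (left + right)
        labels = res.ows_map < mid
        for r in range(10):
            crossing = np.nonzero(np.diff(labels[r].astype(int)))[0]
            assert crossing.size == 1 and abs(crossing[0] - 4) <= 1

    def test_map_mean_equals_per_pixel_recompute(self, uniform_movie):
        stack, _ = uniform_movie
        cat = segment_by_pcl(detect_peaks(tissue_signal(stack)))
        from owsmap.segmentation import window_beats

        spec = WindowSpec(50.0, 150.0)
        res = map_over_pixels(stack, cat, spec, metric="ows")
        beats = window_beats(stack, cat, spec)
        per_pixel = [ows(beats.raw[p]) for p in range(beats.n_pixels)]
        assert res.mean_ows == pytest.approx(np.mean(per_pixel), abs=1e-12)

    def test_single_beat_metric_shapes_and_values(self, uniform_movie):
        stack, _ = uniform_movie
        cat = segment_by_pcl(detect_peaks(tissue_signal(stack)))
        res = map_over_pixels(stack, cat, WindowSpec(50.0, 150.0), metric="single_beat")
        assert res.single_beat_maps.shape[0] == res.single_beat.size
        assert np.all(res.single_beat > 0.99)
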
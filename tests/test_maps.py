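import numpy as np
import pytest

import boutmap as bm
from boutmap.events import STIMULUS_WINDOW, SWIM_WINDOW, extract_windows
from boutmap.exceptions import InvalidParameterError
from boutmap.maps import (
    CorrelationMap,
    average_event_maps,
    combine_across_larvae,
    compute_cluster_map,
    event_pixel_correlation,
    read_map,
    write_map,
)
from boutmap.preprocess import Movie

from conftest import pearson_oracle

FS = 5.81


def movie_with_trace(trace, shape=(6, 6), hot=(2, 3)):
    """Constant movie except one pixel carrying `trace` (shifted positive)."""
    frames = np.full((trace.size, *shape), 10.0)
    frames[:, hot[0], hot[1]] += trace - trace.min()
    return Movie(frames, FS)


class TestEventPixelCorrelation:
    def test_pixel_tracking_centroid_correlates_at_one(self):
        n_pre, n_post = SWIM_WINDOW.window_samples(FS)
        rng = np.random.default_rng(0)
        trace = rng.normal(size=300)
        movie = movie_with_trace(trace)
        onset = 20.0
        idx = int(round(onset * FS))
        centroid = trace[idx - n_pre : idx + n_post]
        r = event_pixel_correlation(movie, centroid, onset, SWIM_WINDOW)
        assert r[2, 3] == pytest.approx(1.0)

    def test_constant_pixel_flagged_undefined(self):
        rng = np.random.default_rng(1)
        trace = rng.normal(size=300)
        movie = movie_with_trace(trace)
        n_pre, n_post = SWIM_WINDOW.window_samples(FS)
        idx = int(round(20.0 * FS))
        r = event_pixel_correlation(movie, trace[idx - n_pre : idx + n_post], 20.0, SWIM_WINDOW)
        assert np.isnan(r[0, 0])
        assert np.isfinite(r[2, 3])

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 50, (200, 4, 5))
        movie = Movie(frames, FS)
        n_pre, n_post = SWIM_WINDOW.window_samples(FS)
        centroid = rng.normal(size=n_pre + n_post)
        onset = 15.0
        r = event_pixel_correlation(movie, centroid, onset, SWIM_WINDOW)
        idx = int(round(onset * FS))
        win = frames[idx - n_pre : idx + n_post]
        for i in range(4):
            for j in range(5):
                assert r[i, j] == pytest.approx(
                    pearson_oracle(win[:, i, j], centroid), abs=1e-10
                )

    def test_invariant_to_affine_intensity_rescaling(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(10, 50, (200, 4, 4))
        centroid = rng.normal(size=sum(SWIM_WINDOW.window_samples(FS)))
        a = event_pixel_correlation(Movie(frames, FS), centroid, 15.0, SWIM_WINDOW)
        b = event_pixel_correlation(Movie(2.0 * frames + 7.0, FS), centroid, 15.0, SWIM_WINDOW)
        assert np.allclose(a, b, atol=1e-9)

    def test_constant_centroid_rejected(self):
        movie = Movie(np.random.default_rng(4).uniform(0, 1, (200, 4, 4)), FS)
        with pytest.raises(InvalidParameterError):
            event_pixel_correlation(movie, np.zeros(sum(SWIM_WINDOW.window_samples(FS))),
                                    15.0, SWIM_WINDOW)


class TestAveraging:
    def test_identical_maps_average_to_themselves(self):
        m = np.random.default_rng(5).uniform(-1, 1, (4, 4))
        assert np.allclose(average_event_maps([m, m, m]), m)

    def test_opposite_correlations_cancel(self):
        m = np.full((3, 3), 0.8)
        out = average_event_maps([m, -m])
        assert np.allclose(out, 0.0)

    def test_nan_excluded_until_all_events_undefined(self):
        a = np.array([[0.5, np.nan], [np.nan, np.nan]])
        b = np.array([[0.7, 0.3], [np.nan, np.nan]])
        out = average_event_maps([a, b])
        assert out[0, 0] == pytest.approx(0.6)
        assert out[0, 1] == pytest.approx(0.3)  # defined in one event only
        assert np.isnan(out[1, 0]) and np.isnan(out[1, 1])


class TestCombineAcrossLarvae:
    def _map(self, value, n_events, shape=(3, 3)):
        return CorrelationMap(np.full(shape, value), cluster_id=0, n_events=n_events)

    def test_single_larva_identity(self):
        m = self._map(0.4, 10)
        out = combine_across_larvae([m])
        assert np.allclose(out.values, m.values)

    def test_equal_maps_any_weights(self):
        out = combine_across_larvae([self._map(0.3, 5), self._map(0.3, 50)])
        assert np.allclose(out.values, 0.3)

    def test_event_count_weighting_matches_hand_computation(self):
        a, b = 0.2, 0.6
        out = combine_across_larvae([self._map(a, 10), self._map(b, 30)])
        assert np.allclose(out.values, (10 * a + 30 * b) / 40.0)
        assert out.n_events == 40

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            combine_across_larvae([self._map(0.1, 1), self._map(0.1, 1, shape=(4, 4))])

    def test_undefined_pixels_drop_their_weight(self):
        m1 = CorrelationMap(np.array([[0.2, np.nan]]), 0, n_events=10)
        m2 = CorrelationMap(np.array([[0.6, 0.4]]), 0, n_events=30)
        out = combine_across_larvae([m1, m2])
        assert out.values[0, 0] == pytest.approx(0.5)
        assert out.values[0, 1] == pytest.approx(0.4)


class TestEndToEndMaps:
    def test_matching_archetype_footprints_light_up(self, default_schedule, small_scene, small_trial):
        """In-footprint mean map value exceeds background for the matching cluster."""
        from boutmap.events import select_stimulus_events, select_swim_events
        from boutmap.preprocess import spatial_mean_filter
        from boutmap.synthetic import NoiseParams

        trace, planted, gt_dff, _ = small_trial
        green, _, _, _ = bm.generate_movie(
            small_scene, default_schedule, planted, noise=NoiseParams(),
            simulate_bleed=False, seed=1,
        )
        filtered = spatial_mean_filter(green, 2)
        stim_ev = select_stimulus_events(default_schedule, STIMULUS_WINDOW)
        i = small_scene.rois_of("stim_on")[0]
        cen = extract_windows(gt_dff[i], FS, stim_ev, STIMULUS_WINDOW).average
        cmap = compute_cluster_map(filtered, cen, stim_ev, STIMULUS_WINDOW)
        fp = small_scene.footprints[small_scene.rois_of("stim_on")].sum(0) > 0
        bg = ~small_scene.footprint_mask()
        assert np.nanmean(cmap.values[fp]) > np.nanmean(cmap.values[bg]) + 0.3

    def test_tiff_sidecar_roundtrip(self, tmp_path):
        values = np.random.default_rng(7).uniform(-1, 1, (5, 6))
        values[0, 0] = np.nan
        cmap = CorrelationMap(values, cluster_id="swim_0", larva_id=3, n_events=17)
        write_map(cmap, tmp_path / "m.tif")
        back = read_map(tmp_path / "m.tif")
        assert back.n_events == 17
        assert back.cluster_id == "swim_0"
        assert np.isnan(back.values[0, 0])
        assert np.allclose(back.values[1:], values[1:], atol=1e-6)
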
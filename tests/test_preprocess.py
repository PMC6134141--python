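import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import boutmap as bm
from boutmap.exceptions import (
    DegenerateBaselineError,
    EstimationFailedError,
    InvalidParameterError,
)
from boutmap.preprocess import (
    BleedthroughCorrector,
    Movie,
    correct_bleedthrough,
    dff,
    estimate_bleedthrough,
    extract_roi_traces,
    spatial_mean_filter,
)
from boutmap.synthetic import NoiseParams


class TestBleedthrough:
    def test_planted_slope_recovered_exactly_without_noise(self):
        rng = np.random.default_rng(0)
        red = rng.uniform(10.0, 200.0, (5, 24, 24))
        green = 0.3 * red
        f = estimate_bleedthrough(Movie(green, 5.81), Movie(red, 5.81, "red"))
        assert f == pytest.approx(0.3, abs=1e-12)

    def test_all_zero_red_channel_fails(self):
        green = np.ones((3, 8, 8))
        with pytest.raises(EstimationFailedError):
            estimate_bleedthrough(Movie(green, 5.81), Movie(np.zeros_like(green), 5.81, "red"))

    def test_factor_recovered_on_synthetic_movie(self, default_schedule, small_scene):
        """Planted bleed factor 0.2 recovered within 0.02 at default noise."""
        trace, planted = bm.generate_tail_trace(default_schedule, 250.0, seed=1)
        green, red, _, _ = bm.generate_movie(
            small_scene, default_schedule, planted, noise=NoiseParams(), seed=1
        )
        f = estimate_bleedthrough(green, red)
        assert f == pytest.approx(small_scene.bleed_factor, abs=0.02)

    def test_zero_factor_is_identity(self):
        rng = np.random.default_rng(1)
        g = Movie(rng.uniform(0, 10, (4, 8, 8)), 5.81)
        r = Movie(rng.uniform(0, 10, (4, 8, 8)), 5.81, "red")
        assert np.array_equal(correct_bleedthrough(g, r, 0.0).frames, g.frames)

    def test_exact_cancellation_gives_zero_movie(self):
        rng = np.random.default_rng(2)
        red = rng.uniform(10, 100, (4, 8, 8))
        out = correct_bleedthrough(Movie(0.3 * red, 5.81), Movie(red, 5.81, "red"), 0.3)
        assert np.allclose(out.frames, 0.0)

    def test_shape_mismatch_rejected(self):
        g = Movie(np.ones((3, 8, 8)), 5.81)
        r = Movie(np.ones((3, 6, 8)), 5.81, "red")
        with pytest.raises(InvalidParameterError):
            correct_bleedthrough(g, r, 0.1)

    def test_reestimation_after_correction_is_near_zero(self, default_schedule, small_scene):
        """Correction is idempotent: the corrected movie has no residual slope."""
        trace, planted = bm.generate_tail_trace(default_schedule, 250.0, seed=1)
        green, red, _, _ = bm.generate_movie(
            small_scene, default_schedule, planted, noise=NoiseParams(0, 0), seed=1
        )
        corr = BleedthroughCorrector().fit_transform(green, red)
        assert estimate_bleedthrough(corr, red) == pytest.approx(0.0, abs=1e-9)


class TestDff:
    def test_constant_trace_maps_to_zeros(self):
        out = dff(np.full(500, 42.0), 5.81)
        assert np.allclose(out, 0.0)

    def test_transient_over_fixed_baseline(self):
        raw = np.full(100, 100.0)
        raw[50] = 150.0
        out = dff(raw, 5.81, f0=100.0)
        assert out.max() == pytest.approx(0.5)
        assert out[0] == pytest.approx(0.0)

    @settings(max_examples=40, deadline=None)
    @given(gain=st.floats(0.1, 100.0))
    def test_invariant_to_multiplicative_gain(self, gain):
        rng = np.random.default_rng(0)
        raw = rng.uniform(50.0, 150.0, 300)
        assert np.allclose(dff(raw, 5.81), dff(gain * raw, 5.81), atol=1e-9)

    def test_zero_baseline_degenerate(self):
        with pytest.raises(DegenerateBaselineError):
            dff(np.zeros(100), 5.81)

    def test_matrix_input_rowwise(self):
        raw = np.vstack([np.full(100, 10.0), np.full(100, 20.0)])
        out = dff(raw, 5.81)
        assert out.shape == raw.shape
        assert np.allclose(out, 0.0)


class TestSpatialMeanFilter:
    def test_constant_frame_unchanged(self):
        m = Movie(np.full((3, 10, 10), 7.0), 5.81)
        assert np.allclose(spatial_mean_filter(m, 2).frames, 7.0)

    def test_unit_impulse_spreads_to_quarter_weights(self):
        frames = np.zeros((1, 9, 9))
        frames[0, 5, 5] = 1.0
        out = spatial_mean_filter(Movie(frames, 5.81), 2).frames[0]
        covered = {(4, 4), (4, 5), (5, 4), (5, 5)}  # windows starting at i cover i..i+1
        assert {tuple(ij) for ij in np.argwhere(out > 0)} == covered
        assert np.allclose(out[out > 0], 0.25)

    def test_interior_mean_preserved(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 10, (2, 20, 20))
        out = spatial_mean_filter(Movie(frames, 5.81), 2).frames
        assert out[:, :-1, :-1].mean() == pytest.approx(frames[:, :-1, :-1].mean(), rel=0.02)

    def test_commutes_with_frame_permutation(self):
        rng = np.random.default_rng(4)
        frames = rng.uniform(0, 10, (5, 12, 12))
        perm = rng.permutation(5)
        a = spatial_mean_filter(Movie(frames[perm], 5.81), 2).frames
        b = spatial_mean_filter(Movie(frames, 5.81), 2).frames[perm]
        assert np.array_equal(a, b)


class TestRoiExtraction:
    def test_uniform_footprint_on_constant_movie(self):
        m = Movie(np.full((4, 8, 8), 3.0), 5.81)
        tr = extract_roi_traces(m, np.ones((1, 8, 8)))
        assert np.allclose(tr, 3.0)

    def test_zero_noise_trace_proportional_to_ground_truth(self, default_schedule, small_scene):
        trace, planted = bm.generate_tail_trace(default_schedule, 250.0, seed=1)
        green, _, gt_dff, _ = bm.generate_movie(
            small_scene, default_schedule, planted, noise=NoiseParams(0, 0),
            simulate_bleed=False, seed=1,
        )
        tr = extract_roi_traces(green, small_scene.footprints)
        for i in range(small_scene.n_rois):
            if np.ptp(gt_dff[i]) == 0:
                assert np.ptp(tr[i]) == pytest.approx(0.0, abs=1e-9)
            else:
                assert np.corrcoef(tr[i], gt_dff[i])[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_footprints_are_independent(self):
        frames = np.zeros((3, 8, 8))
        frames[:, :4, :] = np.arange(3)[:, None, None]  # ROI A region varies
        frames[:, 4:, :] = 5.0                          # ROI B region constant
        wa = np.zeros((8, 8)); wa[:4, :] = 1.0
        wb = np.zeros((8, 8)); wb[4:, :] = 1.0
        tr = extract_roi_traces(Movie(frames, 5.81), np.stack([wa, wb]))
        assert np.allclose(tr[1], 5.0)
        assert np.allclose(tr[0], np.arange(3))

    def test_empty_footprint_rejected(self):
        m = Movie(np.ones((2, 8, 8)), 5.81)
        with pytest.raises(InvalidParameterError):
            extract_roi_traces(m, np.zeros((1, 8, 8)))
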
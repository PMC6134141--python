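import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import boutmap as bm
from boutmap.exceptions import UndefinedAngleError
from boutmap.kinematics import (
    BoutDetector,
    Peaks,
    TailTrace,
    bend_angle,
    bouts_to_frame,
    detect_deflections,
    extract_bouts,
    flag_exclusions,
    read_angle_csv,
    read_points_csv,
    trace_from_points,
)


def straight_tail(tip=(8.0, 0.0)):
    """Nine collinear-ish points from swim bladder (origin) towards the tip."""
    pts = np.zeros((9, 2))
    pts[:, 0] = np.linspace(0.0, tip[0], 9)
    pts[:, 1] = np.linspace(0.0, tip[1], 9)
    return pts


class TestBendAngle:
    def test_collinear_tip_gives_zero(self):
        assert bend_angle(straight_tail(), (1.0, 0.0)) == pytest.approx(0.0)

    def test_equal_axial_and_lateral_offset_gives_45_degrees(self):
        pts = straight_tail()
        pts[8] = (1.0, 1.0)
        assert bend_angle(pts, (1.0, 0.0)) == pytest.approx(45.0)

    def test_mirror_image_flips_sign(self):
        pts = straight_tail()
        pts[8] = (5.0, 2.0)
        mirrored = pts * np.array([1.0, -1.0])
        a = bend_angle(pts, (1.0, 0.0))
        b = bend_angle(mirrored, (1.0, 0.0))
        assert a == pytest.approx(-b)
        assert a != 0.0

    def test_coincident_endpoints_undefined(self):
        pts = straight_tail()
        pts[8] = pts[0]
        with pytest.raises(UndefinedAngleError):
            bend_angle(pts, (1.0, 0.0))

    @settings(max_examples=60, deadline=None)
    @given(
        theta=st.floats(-np.pi, np.pi),
        tip_x=st.floats(1.0, 10.0),
        tip_y=st.floats(-8.0, 8.0),
    )
    def test_equivariant_under_rigid_rotation(self, theta, tip_x, tip_y):
        """Rotating points together with the body axis leaves the angle fixed."""
        pts = straight_tail()
        pts[8] = (tip_x, tip_y)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        a0 = bend_angle(pts, (1.0, 0.0))
        a1 = bend_angle(pts @ R.T, R @ np.array([1.0, 0.0]))
        assert a1 == pytest.approx(a0, abs=1e-9)


class TestDeflectionDetection:
    def test_flat_trace_has_no_peaks(self):
        trace = TailTrace(np.arange(100) / 250.0, np.zeros(100), 250.0)
        assert len(detect_deflections(trace)) == 0

    def test_pure_sinusoid_extrema_count_is_closed_form(self):
        """A 20 Hz, 30 degree, 1 s sinusoid has exactly 40 extrema."""
        t = np.arange(250) / 250.0
        trace = TailTrace(t, 30.0 * np.sin(2 * np.pi * 20.0 * t), 250.0)
        peaks = detect_deflections(trace, min_amplitude_deg=5.0)
        assert len(peaks) == 40
        assert np.sum(peaks.angles > 0) == 20
        assert np.sum(peaks.angles < 0) == 20

    def test_sub_threshold_sinusoid_ignored(self):
        t = np.arange(250) / 250.0
        trace = TailTrace(t, 3.0 * np.sin(2 * np.pi * 20.0 * t), 250.0)
        assert len(detect_deflections(trace, min_amplitude_deg=5.0)) == 0

    def test_empty_trace_gives_empty_result(self):
        trace = TailTrace(np.empty(0), np.empty(0), 250.0)
        assert len(detect_deflections(trace)) == 0


class TestBoutExtraction:
    def _trace(self, n=2500):
        return TailTrace(np.arange(n) / 250.0, np.zeros(n), 250.0)

    def test_no_peaks_no_bouts(self):
        peaks = Peaks(np.empty(0), np.empty(0))
        assert extract_bouts(peaks, self._trace()) == []

    def test_gap_above_threshold_splits_bouts(self):
        peaks = Peaks(
            np.array([1.00, 1.05, 2.00, 2.05]), np.array([20.0, -20.0, 20.0, -20.0])
        )
        bouts = extract_bouts(peaks, self._trace(), max_intrabout_gap_s=0.1)
        assert len(bouts) == 2
        assert bouts[0].n_peaks == 2 and bouts[1].n_peaks == 2

    def test_bouts_disjoint_sorted_nonnegative_interbouts(self, default_schedule):
        trace, _ = bm.generate_tail_trace(default_schedule, 250.0, seed=5)
        bouts = BoutDetector().detect(trace)
        starts = [b.start_s for b in bouts]
        assert starts == sorted(starts)
        for prev, nxt in zip(bouts, bouts[1:]):
            assert nxt.start_s - prev.end_s >= 0.0

    def test_detected_starts_match_planted_within_20ms(self, default_schedule):
        trace, planted = bm.generate_tail_trace(default_schedule, 250.0, seed=1)
        detected = [b for b in BoutDetector().detect(trace) if not b.is_excluded]
        starts = np.array([b.start_s for b in detected])
        for p in planted:
            assert np.abs(starts - p.start_s).min() <= 0.02


class TestExclusions:
    def _bout(self, start, end, peak_angle):
        return bm.Bout(
            start_s=start, end_s=end,
            peak_times=np.array([(start + end) / 2.0]),
            peak_angles=np.array([peak_angle]),
        )

    def test_tracking_gap_flags_tracking_failure(self):
        angles = np.zeros(2500)
        angles[250:500] = np.nan
        trace = TailTrace(np.arange(2500) / 250.0, angles, 250.0)
        flagged = flag_exclusions([self._bout(1.0, 2.0, 20.0)], trace)
        assert flagged[0].excluded == "tracking_failure"

    def test_struggle_amplitude_flags_struggle(self):
        trace = TailTrace(np.arange(2500) / 250.0, np.zeros(2500), 250.0)
        flagged = flag_exclusions(
            [self._bout(1.0, 2.0, 170.0)], trace, struggle_amplitude_deg=100.0
        )
        assert flagged[0].excluded == "struggle"

    def test_normal_bout_not_excluded(self):
        trace = TailTrace(np.arange(2500) / 250.0, np.zeros(2500), 250.0)
        flagged = flag_exclusions([self._bout(1.0, 2.0, 30.0)], trace)
        assert flagged[0].excluded == "none"
        assert not flagged[0].is_excluded


class TestRoundTrips:
    def test_points_csv_roundtrip_and_angle_pipeline(self, tmp_path):
        import pandas as pd

        n = 100
        times = np.arange(n) / 250.0
        pts = np.tile(straight_tail(), (n, 1, 1))
        pts[50, 8] = (8.0, 8.0)  # one bent frame
        df = pd.DataFrame({"frame": np.arange(n), "t_s": times})
        for i in range(9):
            df[f"x{i}"] = pts[:, i, 0]
        for i in range(9):
            df[f"y{i}"] = pts[:, i, 1]
        path = tmp_path / "pts.csv"
        df.to_csv(path, index=False)

        rt_times, rt_pts, rate = read_points_csv(path)
        assert rate == pytest.approx(250.0)
        trace = trace_from_points(rt_times, rt_pts, rate)
        assert trace.angles[0] == pytest.approx(0.0, abs=1e-6)
        assert trace.angles[50] == pytest.approx(45.0, abs=1.0)

    def test_angle_csv_roundtrip(self, tmp_path):
        from boutmap.kinematics import write_tail_trace_csv

        trace = TailTrace(np.arange(100) / 250.0, np.random.default_rng(0).normal(size=100), 250.0)
        path = tmp_path / "angles.csv"
        write_tail_trace_csv(trace, path)
        back = read_angle_csv(path)
        assert np.allclose(back.angles, trace.angles)
        assert back.rate_hz == pytest.approx(250.0)

    def test_bouts_table_columns(self, default_schedule):
        trace, _ = bm.generate_tail_trace(default_schedule, 250.0, seed=0)
        table = bouts_to_frame(BoutDetector().detect(trace))
        assert list(table.columns) == [
            "start_s", "end_s", "n_peaks", "max_abs_angle_deg", "excluded", "reason"
        ]
        assert (table["end_s"] > table["start_s"]).all()
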
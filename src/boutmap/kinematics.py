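"""Tail kinematics: bend angle and swim-bout segmentation.

Larval zebrafish swim in discrete bouts of rhythmic tail oscillation.  The
behaviour camera tracks nine points along the tail (eight segments) from
the caudal end of the swim bladder to the tail tip at the behaviour frame
rate.  This module converts tracked points to a signed bend-angle trace,
detects tail deflection extrema, groups them into bouts, and flags bouts
to be excluded (tracking failures, struggles).

Sign convention: a positive angle is a leftward tail deflection viewed
from below (the tip vector rotated counter-clockwise from the body axis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .exceptions import InvalidParameterError, UndefinedAngleError

__all__ = [
    "TailTrace",
    "Peaks",
    "Bout",
    "bend_angle",
    "estimate_body_axis",
    "trace_from_points",
    "detect_deflections",
    "extract_bouts",
    "flag_exclusions",
    "BoutDetector",
    "bouts_to_frame",
    "read_points_csv",
    "read_angle_csv",
    "write_tail_trace_csv",
]

N_TAIL_POINTS = 9  # swim-bladder end to tail tip, 8 segments


@dataclass
class TailTrace:
    """Uniformly sampled signed bend-angle time series.

    ``angles`` are in degrees; missing tracking frames are NaN.
    ``provenance`` records whether the trace came from tracked points or
    was supplied directly as angles.
    """

    times: np.ndarray
    angles: np.ndarray
    rate_hz: float
    provenance: str = "direct"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.times.shape != self.angles.shape:
            raise InvalidParameterError("times and angles must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if self.rate_hz <= 0:
            raise InvalidParameterError("rate_hz must be > 0")

    @property
    def duration_s(self) -> float:
        return float(self.times.size / self.rate_hz)


@dataclass(frozen=True)
class Peaks:
    """Detected tail-deflection extrema (times in s, signed angles in deg)."""

    times: np.ndarray
    angles: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Bout:
    """One detected swim event, half-open ``[start_s, end_s)``.

    ``excluded`` is ``"none"`` for a retained bout, otherwise the exclusion
    reason (``"tracking_failure"`` or ``"struggle"``).
    """

    start_s: float
    end_s: float
    peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    peak_angles: np.ndarray = field(default_factory=lambda: np.empty(0))
    excluded: str = "none"

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise InvalidParameterError("bout requires start_s < end_s")
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.peak_angles = np.asarray(self.peak_angles, dtype=float)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times.size)

    @property
    def max_abs_angle_deg(self) -> float:
        return float(np.max(np.abs(self.peak_angles))) if self.n_peaks else math.nan

    @property
    def is_excluded(self) -> bool:
        return self.excluded != "none"


def bend_angle(points: np.ndarray, body_axis: np.ndarray) -> float:
    """Signed angle (degrees) between the body axis and the bladder-to-tip vector.

    ``points`` is the (9, 2) array of tracked coordinates ordered from the
    swim-bladder end (index 0) to the tail tip (index 8); only those two
    endpoints enter the angle, matching the definition of the bend angle
    between the swim bladder and the end of the tail.  Result lies in
    (-180, 180]; positive means the tip vector is rotated counter-clockwise
    from ``body_axis``.
    """
    points = np.asarray(points, dtype=float)
    if points.shape != (N_TAIL_POINTS, 2):
        raise InvalidParameterError(f"expected ({N_TAIL_POINTS}, 2) points, got {points.shape}")
    v = points[-1] - points[0]
    if np.allclose(v, 0.0):
        raise UndefinedAngleError("swim-bladder and tail-tip points coincide")
    ax = np.asarray(body_axis, dtype=float)
    cross = ax[0] * v[1] - ax[1] * v[0]
    dot = ax[0] * v[0] + ax[1] * v[1]
    ang = math.degrees(math.atan2(cross, dot))
    return 180.0 if ang == -180.0 else ang


def estimate_body_axis(points_stack: np.ndarray) -> np.ndarray:
    """Resting head-to-tail direction from median point positions over a trial.

    ``points_stack`` has shape (n_frames, 9, 2); NaN frames are ignored.
    The median bladder-to-tip vector is robust to the minority of frames
    in which the tail is bent.
    """
    pts = np.asarray(points_stack, dtype=float)
    v = pts[:, -1, :] - pts[:, 0, :]
    med = np.nanmedian(v, axis=0)
    norm = np.linalg.norm(med)
    if not np.isfinite(norm) or norm == 0:
        raise UndefinedAngleError("cannot estimate body axis: degenerate median vector")
    return med / norm


def trace_from_points(
    times: np.ndarray,
    points_stack: np.ndarray,
    rate_hz: float,
    body_axis: np.ndarray | None = None,
) -> TailTrace:
    """Per-frame bend angle from tracked points; untracked frames become NaN."""
    pts = np.asarray(points_stack, dtype=float)
    if body_axis is None:
        body_axis = estimate_body_axis(pts)
    angles = np.full(pts.shape[0], np.nan)
    for i in range(pts.shape[0]):
        if np.any(~np.isfinite(pts[i])):
            continue
        angles[i] = bend_angle(pts[i], body_axis)
    return TailTrace(times=times, angles=angles, rate_hz=rate_hz, provenance="tracked_points")


def detect_deflections(
    trace: TailTrace,
    min_amplitude_deg: float = 5.0,
    min_interpeak_s: float = 0.01,
) -> Peaks:
    """Alternating-sign local extrema of the bend-angle trace.

    Local maxima and minima with ``|angle| >= min_amplitude_deg`` are kept;
    when two same-sign extrema fall within ``min_interpeak_s`` of each other
    the smaller one is dropped.  NaN samples never host a peak.
    """
    x = trace.angles
    if x.size == 0:
        return Peaks(times=np.empty(0), angles=np.empty(0))
    dist = max(1, int(round(min_interpeak_s * trace.rate_hz)))
    xf = np.where(np.isfinite(x), x, -np.inf)
    maxima, _ = find_peaks(xf, height=min_amplitude_deg, distance=dist)
    xf = np.where(np.isfinite(x), -x, -np.inf)
    minima, _ = find_peaks(xf, height=min_amplitude_deg, distance=dist)

    idx = np.sort(np.concatenate([maxima, minima]))
    kept: list[int] = []
    for i in idx:
        if kept:
            j = kept[-1]
            same_sign = (x[i] > 0) == (x[j] > 0)
            if same_sign and (i - j) < dist:
                if abs(x[i]) > abs(x[j]):
                    kept[-1] = i
                continue
        kept.append(i)
    kept_arr = np.asarray(kept, dtype=int)
    return Peaks(times=trace.times[kept_arr], angles=x[kept_arr])


def extract_bouts(
    peaks: Peaks,
    trace: TailTrace,
    max_intrabout_gap_s: float = 0.1,
    pad_s: float = 0.02,
) -> list[Bout]:
    """Group deflection extrema into bouts.

    Consecutive peaks separated by at most ``max_intrabout_gap_s`` belong to
    one bout; bout boundaries are the first/last peak time padded by
    ``pad_s`` and clipped to the trace extent.
    """
    if len(peaks) == 0:
        return []
    t0 = float(trace.times[0])
    t1 = float(trace.times[-1]) + 1.0 / trace.rate_hz
    bouts: list[Bout] = []
    group_start = 0
    for k in range(1, len(peaks) + 1):
        if k == len(peaks) or peaks.times[k] - peaks.times[k - 1] > max_intrabout_gap_s:
            pt = peaks.times[group_start:k]
            pa = peaks.angles[group_start:k]
            bouts.append(
                Bout(
                    start_s=max(t0, float(pt[0]) - pad_s),
                    end_s=min(t1, float(pt[-1]) + pad_s),
                    peak_times=pt,
                    peak_angles=pa,
                )
            )
            group_start = k
    return bouts


def flag_exclusions(
    bouts: list[Bout],
    trace: TailTrace,
    struggle_amplitude_deg: float = 100.0,
    nan_fraction: float = 0.2,
) -> list[Bout]:
    """Flag bouts over tracking gaps or with struggle-scale deflections.

    A bout whose in-bout NaN fraction exceeds ``nan_fraction`` is flagged
    ``tracking_failure``; one whose largest absolute peak angle exceeds
    ``struggle_amplitude_deg`` is flagged ``struggle``.  Flagged bouts are
    retained in the list but excluded from downstream event sets.
    """
    out: list[Bout] = []
    for b in bouts:
        sel = (trace.times >= b.start_s) & (trace.times < b.end_s)
        frac_nan = float(np.mean(~np.isfinite(trace.angles[sel]))) if np.any(sel) else 1.0
        if frac_nan > nan_fraction:
            out.append(replace(b, excluded="tracking_failure"))
        elif b.n_peaks and b.max_abs_angle_deg > struggle_amplitude_deg:
            out.append(replace(b, excluded="struggle"))
        else:
            out.append(replace(b, excluded="none"))
    return out


class BoutDetector(BaseEstimator):
    """Detect swim bouts in a bend-angle trace.

    A stateless transformer-style estimator: :meth:`detect` runs extrema
    detection, bout grouping and exclusion flagging with the configured
    thresholds.  Thresholds are exposed as parameters so the detector
    composes with sklearn parameter search utilities.

    Parameters
    ----------
    min_amplitude_deg : float
        Minimum absolute deflection for an extremum to count (deg).
    min_interpeak_s : float
        Minimum separation of same-sign extrema (s).
    max_intrabout_gap_s : float
        Largest inter-peak gap kept within one bout (s).
    pad_s : float
        Padding added before the first and after the last peak (s).
    struggle_amplitude_deg : float
        Peak amplitude above which a bout is flagged as a struggle (deg).
    nan_fraction : float
        In-bout missing-frame fraction above which a bout is flagged as a
        tracking failure.
    """

    def __init__(
        self,
        min_amplitude_deg: float = 5.0,
        min_interpeak_s: float = 0.01,
        max_intrabout_gap_s: float = 0.1,
        pad_s: float = 0.02,
        struggle_amplitude_deg: float = 100.0,
        nan_fraction: float = 0.2,
    ):
        self.min_amplitude_deg = min_amplitude_deg
        self.min_interpeak_s = min_interpeak_s
        self.max_intrabout_gap_s = max_intrabout_gap_s
        self.pad_s = pad_s
        self.struggle_amplitude_deg = struggle_amplitude_deg
        self.nan_fraction = nan_fraction

    def detect(self, trace: TailTrace) -> list[Bout]:
        peaks = detect_deflections(trace, self.min_amplitude_deg, self.min_interpeak_s)
        bouts = extract_bouts(peaks, trace, self.max_intrabout_gap_s, self.pad_s)
        return flag_exclusions(bouts, trace, self.struggle_amplitude_deg, self.nan_fraction)

    # transformer-flavoured alias so the detector slots into generic code
    def transform(self, trace: TailTrace) -> list[Bout]:
        return self.detect(trace)


def bouts_to_frame(bouts: list[Bout]) -> pd.DataFrame:
    """Tabulate bouts (one row each) for CSV export."""
    return pd.DataFrame(
        {
            "start_s": [b.start_s for b in bouts],
            "end_s": [b.end_s for b in bouts],
            "n_peaks": [b.n_peaks for b in bouts],
            "max_abs_angle_deg": [b.max_abs_angle_deg for b in bouts],
            "excluded": [b.is_excluded for b in bouts],
            "reason": [b.excluded for b in bouts],
        }
    )


def read_points_csv(path) -> tuple[np.ndarray, np.ndarray, float]:
    """Read tracked points CSV (frame, t_s, x0..x8, y0..y8).

    Returns (times, points_stack, rate_hz).
    """
    df = pd.read_csv(path)
    times = df["t_s"].to_numpy(dtype=float)
    xs = df[[f"x{i}" for i in range(N_TAIL_POINTS)]].to_numpy(dtype=float)
    ys = df[[f"y{i}" for i in range(N_TAIL_POINTS)]].to_numpy(dtype=float)
    pts = np.stack([xs, ys], axis=-1)
    if times.size < 2:
        raise InvalidParameterError("need at least two frames to infer the frame rate")
    rate = 1.0 / float(np.median(np.diff(times)))
    return times, pts, rate


def read_angle_csv(path) -> TailTrace:
    """Read a 2-column bend-angle CSV (time_s, angle_deg)."""
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(dtype=float)
    if times.size < 2:
        raise InvalidParameterError("need at least two samples to infer the frame rate")
    rate = 1.0 / float(np.median(np.diff(times)))
    return TailTrace(times=times, angles=df["angle_deg"].to_numpy(dtype=float), rate_hz=rate)


def write_tail_trace_csv(trace: TailTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "angle_deg": trace.angles}).to_csv(path, index=False)
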
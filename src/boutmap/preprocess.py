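"""Movie preprocessing: bleed-through correction, dF/F, spatial filtering.

The green (GCaMP) channel carries a low level of bleed-through from the
red (DsRed/mCherry) anatomy channel.  The bleed factor is the slope of a
robust line through the scatter of green vs. red pixel values over
red-dominated pixels; correction subtracts ``factor * red`` per pixel and
clips at zero.  dF/F uses a sliding-percentile baseline by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (
    DegenerateBaselineError,
    EstimationFailedError,
    InvalidParameterError,
)

__all__ = [
    "Movie",
    "estimate_bleedthrough",
    "correct_bleedthrough",
    "BleedthroughCorrector",
    "dff",
    "DffTransformer",
    "spatial_mean_filter",
    "SpatialMeanFilter",
    "extract_roi_traces",
]

log = logging.getLogger(__name__)


@dataclass
class Movie:
    """A single-channel frame stack (time, rows, cols) at a fixed rate."""

    frames: np.ndarray
    frame_rate_hz: float
    channel: str = "green"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (time, rows, cols) array")
        if self.frame_rate_hz <= 0:
            raise InvalidParameterError("frame_rate_hz must be > 0")
        if np.any(self.frames < 0):
            raise InvalidParameterError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def _mean_images(green: Movie | np.ndarray, red: Movie | np.ndarray):
    g = green.frames if isinstance(green, Movie) else np.asarray(green, dtype=float)
    r = red.frames if isinstance(red, Movie) else np.asarray(red, dtype=float)
    if g.ndim == 3:
        g = g.mean(axis=0)
    if r.ndim == 3:
        r = r.mean(axis=0)
    if g.shape != r.shape:
        raise InvalidParameterError("green and red shapes differ")
    return g, r


def estimate_bleedthrough(
    green: Movie | np.ndarray,
    red: Movie | np.ndarray,
    red_percentile: float = 90.0,
    max_pixels: int = 20000,
) -> float:
    """Red-to-green bleed-through factor.

    The Theil-Sen slope of green vs. red time-averaged pixel values,
    restricted to pixels above the red channel's ``red_percentile`` (the
    reproducible analogue of reading a slope off the two-channel scatter
    plot).  Raises :class:`EstimationFailedError` when there are no
    red-positive pixels or the selected red values carry no spread.
    """
    g, r = _mean_images(green, red)
    if not np.any(r > 0):
        raise EstimationFailedError("no red-positive pixels")
    thr = np.percentile(r, red_percentile)
    sel = r >= thr
    rv, gv = r[sel], g[sel]
    if rv.size > max_pixels:
        # deterministic thinning, spread across the red intensity range
        order = np.argsort(rv, kind="stable")
        pick = order[np.linspace(0, rv.size - 1, max_pixels).astype(int)]
        rv, gv = rv[pick], gv[pick]
    if np.ptp(rv) == 0:
        raise EstimationFailedError("selected red pixels have zero spread")
    slope, _, _, _ = stats.theilslopes(gv, rv)
    return float(max(slope, 0.0))


def correct_bleedthrough(
    green: Movie, red: Movie, factor: float
) -> Movie:
    """Subtract ``factor * red`` from the green channel, clipped at zero."""
    if factor < 0:
        raise InvalidParameterError("bleed-through factor must be >= 0")
    if green.frames.shape != red.frames.shape:
        raise InvalidParameterError("green and red movies must share a shape")
    out = np.maximum(green.frames - factor * red.frames, 0.0)
    return Movie(frames=out, frame_rate_hz=green.frame_rate_hz, channel=green.channel)


class BleedthroughCorrector(TransformerMixin, BaseEstimator):
    """Estimate and remove red-to-green channel bleed-through.

    ``fit(green, red)`` estimates ``factor_``; ``transform(green, red)``
    subtracts the scaled red channel.  A fixed ``factor`` parameter skips
    estimation.
    """

    def __init__(self, factor: float | None = None, red_percentile: float = 90.0,
                 max_pixels: int = 20000):
        self.factor = factor
        self.red_percentile = red_percentile
        self.max_pixels = max_pixels

    def fit(self, green: Movie, red: Movie):
        if self.factor is not None:
            self.factor_ = float(self.factor)
        else:
            self.factor_ = estimate_bleedthrough(
                green, red, self.red_percentile, self.max_pixels
            )
        return self

    def transform(self, green: Movie, red: Movie) -> Movie:
        if not hasattr(self, "factor_"):
            raise RuntimeError("BleedthroughCorrector is not fitted")
        return correct_bleedthrough(green, red, self.factor_)

    def fit_transform(self, green: Movie, red: Movie) -> Movie:  # type: ignore[override]
        return self.fit(green, red).transform(green, red)


def dff(
    raw: np.ndarray,
    frame_rate_hz: float,
    method: str = "sliding_percentile",
    window_s: float = 30.0,
    percentile: float = 10.0,
    f0: float | np.ndarray | None = None,
) -> np.ndarray:
    """Fractional fluorescence change (F - F0) / F0.

    ``raw`` may be a single trace or an (n_traces, n_frames) matrix.  The
    default baseline is the 10th percentile over a sliding 30 s window
    (robust in activity-dense trials); ``method="global_percentile"`` uses
    one scalar per trace, and an explicit ``f0`` overrides both.
    """
    raw = np.asarray(raw, dtype=float)
    squeeze = raw.ndim == 1
    X = raw[None, :] if squeeze else raw
    if f0 is not None:
        base = np.broadcast_to(np.asarray(f0, dtype=float), X.shape)
    elif method == "sliding_percentile":
        win = max(1, int(round(window_s * frame_rate_hz)))
        win = min(win, X.shape[1])
        base = ndimage.percentile_filter(X, percentile=percentile, size=(1, win),
                                         mode="nearest")
    elif method == "global_percentile":
        base = np.broadcast_to(
            np.percentile(X, percentile, axis=1, keepdims=True), X.shape
        )
    else:
        raise InvalidParameterError(f"unknown baseline method {method!r}")
    if np.any(base <= 0):
        raise DegenerateBaselineError("baseline F0 <= 0")
    out = (X - base) / base
    return out[0] if squeeze else out


class DffTransformer(TransformerMixin, BaseEstimator):
    """Transform raw fluorescence traces to dF/F (stateless)."""

    def __init__(self, method: str = "sliding_percentile", window_s: float = 30.0,
                 percentile: float = 10.0):
        self.method = method
        self.window_s = window_s
        self.percentile = percentile

    def fit(self, X, y=None):
        return self

    def transform(self, X, frame_rate_hz: float | None = None):
        if frame_rate_hz is None:
            raise InvalidParameterError("frame_rate_hz is required")
        return dff(X, frame_rate_hz, self.method, self.window_s, self.percentile)


def spatial_mean_filter(movie: Movie, size_px: int = 2) -> Movie:
    """Per-frame uniform mean filter with nearest-replication edges.

    For the default even size the window is anchored top-left:
    ``out[i, j] = mean(frame[i:i+2, j:j+2])``.
    """
    if size_px < 1:
        raise InvalidParameterError("size_px must be >= 1")
    if size_px == 1:
        return Movie(movie.frames.copy(), movie.frame_rate_hz, movie.channel)
    # ndimage's even-size window ends at i; a negative origin shifts it so
    # the window starts at i (no shift needed for odd, centred sizes).
    origin = 0 if size_px % 2 else -(size_px // 2)
    out = ndimage.uniform_filter(
        movie.frames, size=(1, size_px, size_px), mode="nearest",
        origin=(0, origin, origin),
    )
    return Movie(frames=out, frame_rate_hz=movie.frame_rate_hz, channel=movie.channel)


class SpatialMeanFilter(TransformerMixin, BaseEstimator):
    """Stateless per-frame spatial mean filter."""

    def __init__(self, size_px: int = 2):
        self.size_px = size_px

    def fit(self, X, y=None):
        return self

    def transform(self, movie: Movie) -> Movie:
        return spatial_mean_filter(movie, self.size_px)


def extract_roi_traces(movie: Movie, footprints: np.ndarray) -> np.ndarray:
    """Weighted-mean pixel intensity under each footprint, per frame.

    A naive footprint-averaging extractor: the pipeline accepts traces
    from any source-extraction method, and this provides the plumbing for
    footprints of known geometry.  Returns an (n_rois, n_frames) array.
    """
    W = np.asarray(footprints, dtype=float)
    if W.ndim == 2:
        W = W[None]
    if W.shape[1:] != movie.frame_shape:
        raise InvalidParameterError("footprints do not match the frame shape")
    sums = W.sum(axis=(1, 2))
    if np.any(sums <= 0):
        raise InvalidParameterError("empty footprint")
    n_px = movie.frame_shape[0] * movie.frame_shape[1]
    F = movie.frames.reshape(movie.n_frames, n_px)
    traces = (F @ W.reshape(W.shape[0], n_px).T) / sums
    return traces.T
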
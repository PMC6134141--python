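"""Pixel-wise cluster correlation maps.

Each cluster centroid is used as a regressor against the spatially
filtered movie: for every event (swim bout or stimulus presentation) the
Pearson correlation between each pixel's time series within the event
window and the centroid is computed, and the per-event maps are averaged
into the final correlation map.  Maps from several larvae, registered to
a common space externally, are combined by a weighted per-pixel mean
(weights default to each larva's event count).

Per-event correlations use the raw filtered intensities: Pearson
correlation is invariant to the per-window affine dF/F transform, so
correlating intensities and correlating dF/F give the same map.
Zero-variance pixels within a window are undefined (NaN), excluded from
averages, and undefined in the final map only if undefined in every event.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .events import EventWindowSpec
from .exceptions import InvalidParameterError
from .preprocess import Movie

__all__ = [
    "CorrelationMap",
    "event_pixel_correlation",
    "average_event_maps",
    "compute_cluster_map",
    "combine_across_larvae",
    "write_map",
    "read_map",
]


@dataclass
class CorrelationMap:
    """Per-pixel mean correlation with one cluster centroid.

    ``values`` is a 2-D float image in [-1, 1]; undefined pixels are NaN.
    """

    values: np.ndarray
    cluster_id: int | str
    larva_id: int | str = 0
    n_events: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("map values must be a 2-D image")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1.0 - 1e-9 or finite.max() > 1.0 + 1e-9):
            raise InvalidParameterError("defined correlations must lie in [-1, 1]")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def event_pixel_correlation(
    movie: Movie,
    centroid: np.ndarray,
    event_onset_s: float,
    spec: EventWindowSpec,
) -> np.ndarray:
    """Per-pixel Pearson correlation with the centroid in one event window.

    The window is cut with the same frame snapping as
    :func:`boutmap.events.extract_windows`; the centroid must have the
    window's length.  Zero-variance pixels get NaN.
    """
    centroid = np.asarray(centroid, dtype=float)
    fs = movie.frame_rate_hz
    n_pre, n_post = spec.window_samples(fs)
    L = n_pre + n_post
    if centroid.size != L:
        raise InvalidParameterError(
            f"centroid length {centroid.size} != window frame count {L}"
        )
    if np.ptp(centroid) == 0:
        raise InvalidParameterError("constant centroid: correlation undefined")
    idx = int(round(event_onset_s * fs))
    lo, hi = idx - n_pre, idx + n_post
    if lo < 0 or hi > movie.n_frames:
        raise InvalidParameterError("event window exits the movie")

    W = movie.frames[lo:hi].reshape(L, -1)
    Wc = W - W.mean(axis=0)
    sd = W.std(axis=0)
    c = centroid - centroid.mean()
    csd = centroid.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Wc.T @ c) / (L * sd * csd)
    r[sd == 0] = np.nan
    return r.reshape(movie.frame_shape)


def average_event_maps(maps: list[np.ndarray]) -> np.ndarray:
    """Per-pixel mean over per-event maps, ignoring NaN.

    A pixel stays NaN only when it is undefined in every event.
    """
    if not maps:
        raise InvalidParameterError("need at least one event map")
    stack = np.asarray(maps, dtype=float)
    defined = np.isfinite(stack)
    n_def = defined.sum(axis=0)
    total = np.where(defined, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = total / n_def
    out[n_def == 0] = np.nan
    return out


def compute_cluster_map(
    movie: Movie,
    centroid: np.ndarray,
    event_onsets: np.ndarray,
    spec: EventWindowSpec,
    cluster_id: int | str = 0,
    larva_id: int | str = 0,
) -> CorrelationMap:
    """Final correlation map for one cluster: per-event maps averaged.

    Events whose window does not fit inside the movie are skipped.
    """
    per_event = []
    for t in np.atleast_1d(np.asarray(event_onsets, dtype=float)):
        try:
            per_event.append(event_pixel_correlation(movie, centroid, t, spec))
        except InvalidParameterError:
            continue
    if not per_event:
        raise InvalidParameterError("no event window fits inside the movie")
    return CorrelationMap(
        values=average_event_maps(per_event),
        cluster_id=cluster_id,
        larva_id=larva_id,
        n_events=len(per_event),
    )


def combine_across_larvae(
    maps: list[CorrelationMap], weights: np.ndarray | None = None
) -> CorrelationMap:
    """Weighted per-pixel mean of pre-registered maps from several larvae.

    Default weights are proportional to each larva's event count.  At each
    pixel the weights of undefined contributions are dropped and the rest
    renormalized; a pixel undefined everywhere stays undefined.
    """
    if not maps:
        raise InvalidParameterError("need at least one map")
    shape = maps[0].values.shape
    if any(m.values.shape != shape for m in maps):
        raise InvalidParameterError("maps must share a shape")
    if weights is None:
        weights = np.asarray([m.n_events for m in maps], dtype=float)
    else:
        weights = np.asarray(weights, dtype=float)
    if weights.size != len(maps) or np.any(weights < 0) or weights.sum() == 0:
        raise InvalidParameterError("invalid weights")

    stack = np.asarray([m.values for m in maps])
    defined = np.isfinite(stack)
    w = weights[:, None, None] * defined
    wsum = w.sum(axis=0)
    vals = np.where(defined, stack, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (w * vals).sum(axis=0) / wsum
    out[wsum == 0] = np.nan
    return CorrelationMap(
        values=out,
        cluster_id=maps[0].cluster_id,
        larva_id="combined",
        n_events=int(sum(m.n_events for m in maps)),
    )


def write_map(cmap: CorrelationMap, path) -> None:
    """Write a map as 32-bit float TIFF with a JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, cmap.values.astype(np.float32))
    sidecar = {
        "cluster_id": cmap.cluster_id,
        "larva_id": cmap.larva_id,
        "n_events": cmap.n_events,
        "n_undefined_pixels": int((~cmap.defined_mask).sum()),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_map(path) -> CorrelationMap:
    import tifffile

    path = Path(path)
    values = tifffile.imread(path).astype(float)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    return CorrelationMap(
        values=values,
        cluster_id=sidecar["cluster_id"],
        larva_id=sidecar["larva_id"],
        n_events=sidecar["n_events"],
    )
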
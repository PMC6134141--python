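"""Swim-driven vs. stimulus-driven trace classification.

For each ROI the mean event-wise correlation of its triggered windows
with their own triggered average measures how consistently the calcium
signal changes around that event class.  A trace is swim-driven when its
mean correlation with the swim-triggered average exceeds the threshold
(default 0.6) but its stimulus correlation does not, stimulus-driven in
the opposite case, ambiguous when both exceed the threshold (excluded
from clustering), and unclassified otherwise.  The two scores are not
independent — bouts occur preferentially during stimulus motion — and no
decorrelation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .events import (
    STIMULUS_WINDOW,
    SWIM_WINDOW,
    EventWindowSpec,
    TriggeredSet,
    extract_windows,
)
from .exceptions import EmptyEventSetError, InvalidParameterError

__all__ = [
    "CATEGORIES",
    "TraceClassification",
    "mean_event_correlation",
    "classify_trace",
    "TraceClassifier",
    "classify_rois",
]

log = logging.getLogger(__name__)

CATEGORIES = ("swim_driven", "stimulus_driven", "ambiguous", "unclassified")


@dataclass(frozen=True)
class TraceClassification:
    """Scores and category for one ROI trace."""

    roi_id: int
    r_swim: float | None
    r_stim: float | None
    category: str


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "pearson":
        return float(np.corrcoef(a, b)[0, 1])
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise InvalidParameterError(f"unknown correlation method {method!r}")


def mean_event_correlation(
    triggered: TriggeredSet, method: str = "pearson"
) -> float | None:
    """Mean over events of corr(segment, set average).

    With fewer than two events the segment equals the average and the
    score is degenerate: ``None`` is returned.  A zero-variance segment
    (or a zero-variance average) contributes a correlation of 0 and is
    counted; the occurrence is logged.
    """
    if triggered.n_events < 2:
        return None
    avg = triggered.average
    avg_flat = np.ptp(avg) == 0
    rs = []
    for seg in triggered.segments:
        if avg_flat or np.ptp(seg) == 0:
            log.info("zero-variance segment or average: correlation counted as 0")
            rs.append(0.0)
        else:
            rs.append(_corr(seg, avg, method))
    return float(np.mean(rs))


def classify_trace(
    r_swim: float | None, r_stim: float | None, threshold: float = 0.6
) -> str:
    """Apply the correlation-threshold rule (strict inequalities).

    An undefined score (``None`` or NaN) makes the trace unclassified.
    """
    if r_swim is None or r_stim is None or np.isnan(r_swim) or np.isnan(r_stim):
        return "unclassified"
    swim_hi = r_swim > threshold
    stim_hi = r_stim > threshold
    if swim_hi and stim_hi:
        return "ambiguous"
    if swim_hi:
        return "swim_driven"
    if stim_hi:
        return "stimulus_driven"
    return "unclassified"


class TraceClassifier(BaseEstimator):
    """Classify ROI traces from their event-consistency scores.

    A stateless sklearn-style classifier over precomputed score pairs:
    ``predict(X)`` maps an (n, 2) array of ``(r_swim, r_stim)`` scores to
    categories.  :meth:`score_trace` computes the scores for one dF/F
    trace given the admissible event onsets.

    Parameters
    ----------
    threshold : float
        Correlation threshold for the driven categories (default 0.6).
    method : str
        Event-wise correlation: ``"pearson"`` (default) or ``"spearman"``.
    """

    def __init__(self, threshold: float = 0.6, method: str = "pearson"):
        self.threshold = threshold
        self.method = method

    def fit(self, X=None, y=None):
        if not 0.0 < self.threshold <= 1.0:
            raise InvalidParameterError("threshold must be in (0, 1]")
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidParameterError("expected an (n, 2) array of (r_swim, r_stim)")
        return np.asarray(
            [classify_trace(rs, rt, self.threshold) for rs, rt in X], dtype=object
        )

    def score_trace(
        self,
        trace: np.ndarray,
        frame_rate_hz: float,
        swim_events: np.ndarray,
        stim_events: np.ndarray,
        swim_spec: EventWindowSpec = SWIM_WINDOW,
        stim_spec: EventWindowSpec = STIMULUS_WINDOW,
    ) -> tuple[float | None, float | None, TriggeredSet | None, TriggeredSet | None]:
        """(r_swim, r_stim, swim TriggeredSet, stimulus TriggeredSet)."""

        def one(events, spec):
            try:
                ts = extract_windows(trace, frame_rate_hz, events, spec)
            except EmptyEventSetError:
                return None, None
            return mean_event_correlation(ts, self.method), ts

        r_swim, swim_set = one(swim_events, swim_spec)
        r_stim, stim_set = one(stim_events, stim_spec)
        return r_swim, r_stim, swim_set, stim_set


def classify_rois(
    dff: np.ndarray,
    frame_rate_hz: float,
    swim_events: np.ndarray,
    stim_events: np.ndarray,
    threshold: float = 0.6,
    method: str = "pearson",
    swim_spec: EventWindowSpec = SWIM_WINDOW,
    stim_spec: EventWindowSpec = STIMULUS_WINDOW,
) -> tuple[pd.DataFrame, dict[int, TriggeredSet], dict[int, TriggeredSet]]:
    """Score and classify every ROI trace in a dF/F matrix.

    Returns a classification table (roi_id, r_swim, r_stim, category) and
    the per-ROI swim/stimulus triggered sets for downstream clustering.
    """
    clf = TraceClassifier(threshold=threshold, method=method).fit()
    rows, swim_sets, stim_sets = [], {}, {}
    for i, trace in enumerate(np.atleast_2d(np.asarray(dff, dtype=float))):
        r_swim, r_stim, swim_set, stim_set = clf.score_trace(
            trace, frame_rate_hz, swim_events, stim_events, swim_spec, stim_spec
        )
        if swim_set is not None:
            swim_sets[i] = swim_set
        if stim_set is not None:
            stim_sets[i] = stim_set
        rows.append(
            {
                "roi_id": i,
                "r_swim": np.nan if r_swim is None else r_swim,
                "r_stim": np.nan if r_stim is None else r_stim,
                "category": classify_trace(r_swim, r_stim, threshold),
            }
        )
    return pd.DataFrame(rows), swim_sets, stim_sets
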
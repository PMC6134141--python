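"""Swim- and stimulus-triggered event windows and their averages.

Swim events are bout starts that follow the previous bout by more than a
minimum gap (default 0.5 s, measured from the previous bout's end) and
whose full window (default 2 s before to 5 s after onset) lies inside the
trial.  Stimulus events are motion onsets windowed 5 s before onset to the
end of the 10 s motion period.  Windows partially outside the trial are
dropped, never padded.

Event times live on the 250 Hz behaviour clock and are snapped to the
nearest imaging frame (default 5.81 Hz) when windows are cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyEventSetError, InvalidParameterError
from .stimulus import StimulusSchedule

__all__ = [
    "EventWindowSpec",
    "SWIM_WINDOW",
    "STIMULUS_WINDOW",
    "TriggeredSet",
    "select_swim_events",
    "select_stimulus_events",
    "select_events",
    "extract_windows",
]


@dataclass(frozen=True)
class EventWindowSpec:
    """Window geometry around one event class.

    ``min_gap_from_previous_s`` applies to swim events only and is measured
    from the previous bout's end to the candidate bout's start.
    """

    event_kind: str
    pre_s: float
    post_s: float
    min_gap_from_previous_s: float | None = None

    def __post_init__(self) -> None:
        if self.event_kind not in ("swim", "stimulus"):
            raise InvalidParameterError("event_kind must be 'swim' or 'stimulus'")
        if self.pre_s < 0 or self.post_s < 0:
            raise InvalidParameterError("pre_s and post_s must be >= 0")

    def window_samples(self, rate_hz: float) -> tuple[int, int]:
        """(n_pre, n_post) samples at ``rate_hz``; window length is their sum."""
        return int(round(self.pre_s * rate_hz)), int(round(self.post_s * rate_hz))


SWIM_WINDOW = EventWindowSpec("swim", pre_s=2.0, post_s=5.0, min_gap_from_previous_s=0.5)
STIMULUS_WINDOW = EventWindowSpec("stimulus", pre_s=5.0, post_s=10.0)


@dataclass
class TriggeredSet:
    """Per-event trace windows aligned on event onset, plus their mean.

    ``segments`` has shape (n_events, n_samples); ``offsets_s`` is the
    common time axis relative to onset; ``average`` is the element-wise
    mean over events.
    """

    segments: np.ndarray
    event_times: np.ndarray
    offsets_s: np.ndarray
    average: np.ndarray

    @property
    def n_events(self) -> int:
        return self.segments.shape[0]

    def sem(self) -> np.ndarray:
        """Per-timepoint standard error of the mean over events."""
        if self.n_events < 2:
            return np.zeros(self.segments.shape[1])
        return self.segments.std(axis=0, ddof=1) / np.sqrt(self.n_events)


def select_swim_events(
    bouts, spec: EventWindowSpec, trial_duration: float
) -> np.ndarray:
    """Admissible bout-start times.

    ``bouts`` must already exclude flagged ones (see
    :func:`boutmap.kinematics.flag_exclusions`); any bout exposing a true
    ``is_excluded`` is skipped here as a safety net.
    """
    gap = spec.min_gap_from_previous_s or 0.0
    onsets = []
    prev_end = -np.inf
    for b in sorted(bouts, key=lambda b: b.start_s):
        if getattr(b, "is_excluded", False):
            continue
        admissible = (
            b.start_s - prev_end > gap
            and b.start_s - spec.pre_s >= 0.0
            and b.start_s + spec.post_s <= trial_duration
        )
        if admissible:
            onsets.append(b.start_s)
        prev_end = b.end_s
    return np.asarray(onsets)


def select_stimulus_events(
    schedule: StimulusSchedule, spec: EventWindowSpec
) -> np.ndarray:
    """Motion onsets whose full window fits inside the trial."""
    onsets = [
        t_on
        for t_on in schedule.onsets()
        if t_on - spec.pre_s >= 0.0 and t_on + spec.post_s <= schedule.trial_duration
    ]
    return np.asarray(onsets)


def select_events(
    spec: EventWindowSpec,
    bouts=None,
    schedule: StimulusSchedule | None = None,
    trial_duration: float | None = None,
) -> np.ndarray:
    """Dispatch on the event kind."""
    if spec.event_kind == "swim":
        if bouts is None or trial_duration is None:
            raise InvalidParameterError("swim events need bouts and trial_duration")
        return select_swim_events(bouts, spec, trial_duration)
    if schedule is None:
        raise InvalidParameterError("stimulus events need a schedule")
    return select_stimulus_events(schedule, spec)


def extract_windows(
    trace: np.ndarray,
    frame_rate_hz: float,
    events: np.ndarray,
    spec: EventWindowSpec,
) -> TriggeredSet:
    """Cut equal-length windows around each event and average them.

    Each event is snapped to the nearest imaging frame; windows that do
    not fully fit in the trace are dropped.  Raises
    :class:`EmptyEventSetError` when no admissible window remains — the
    caller treats such a trace as unclassifiable.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    n_pre, n_post = spec.window_samples(frame_rate_hz)
    if n_pre + n_post < 1:
        raise InvalidParameterError("window must span at least one sample")
    segments, kept_times = [], []
    for t in np.atleast_1d(np.asarray(events, dtype=float)):
        idx = int(round(t * frame_rate_hz))
        lo, hi = idx - n_pre, idx + n_post
        if lo < 0 or hi > n:
            continue
        segments.append(trace[lo:hi])
        kept_times.append(t)
    if not segments:
        raise EmptyEventSetError("no admissible events for this trace")
    seg = np.asarray(segments)
    offsets = (np.arange(-n_pre, n_post)) / frame_rate_hz
    return TriggeredSet(
        segments=seg,
        event_times=np.asarray(kept_times),
        offsets_s=offsets,
        average=seg.mean(axis=0),
    )
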
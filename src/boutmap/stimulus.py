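"""Optomotor stimulus schedules.

A trial presents a whole-field moving grating in open loop: repeated cycles
of a static presentation followed by a motion period.  The default protocol
is a 315 s single-plane trial tiling 10 s of caudal-to-rostral motion with
5 s of static grating, starting with a static period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import InvalidParameterError

__all__ = ["StimulusSchedule", "make_schedule"]


@dataclass(frozen=True)
class StimulusSchedule:
    """Motion on/off intervals within one trial.

    Parameters
    ----------
    trial_duration : float
        Trial length in seconds.
    intervals : list of (float, float)
        Half-open ``[t_on, t_off)`` motion periods, sorted, non-overlapping,
        contained in ``[0, trial_duration)``.
    """

    trial_duration: float
    intervals: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.trial_duration <= 0:
            raise InvalidParameterError("trial_duration must be > 0")
        prev_off = 0.0
        for t_on, t_off in self.intervals:
            if not (0.0 <= t_on < t_off <= self.trial_duration):
                raise InvalidParameterError(
                    f"interval [{t_on}, {t_off}) not contained in "
                    f"[0, {self.trial_duration})"
                )
            if t_on < prev_off:
                raise InvalidParameterError("intervals overlap or are unsorted")
            prev_off = t_off

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def onsets(self) -> list[float]:
        """Motion onset times in seconds."""
        return [t_on for t_on, _ in self.intervals]

    def is_motion(self, t: float) -> bool:
        """True if the grating is moving at time ``t`` (half-open intervals)."""
        return any(t_on <= t < t_off for t_on, t_off in self.intervals)

    def motion_mask(self, times) -> "np.ndarray":
        """Boolean mask of motion for an array of sample times."""
        import numpy as np

        times = np.asarray(times, dtype=float)
        mask = np.zeros(times.shape, dtype=bool)
        for t_on, t_off in self.intervals:
            mask |= (times >= t_on) & (times < t_off)
        return mask

    def total_motion_s(self) -> float:
        return sum(t_off - t_on for t_on, t_off in self.intervals)


def make_schedule(
    trial_duration: float, motion_s: float = 10.0, static_s: float = 5.0
) -> StimulusSchedule:
    """Tile a trial with alternating static/motion periods.

    Cycles of ``static_s`` static followed by ``motion_s`` motion are tiled
    from t = 0, so the first motion onset is at ``static_s``.  A trailing
    motion period that would run past the trial end is truncated at the
    trial end; a cycle whose motion onset falls at or after the trial end
    contributes no interval.

    Examples
    --------
    >>> make_schedule(315, 10, 5).n_intervals
    21
    """
    if trial_duration <= 0 or motion_s <= 0 or static_s <= 0:
        raise InvalidParameterError("all durations must be > 0")
    intervals = []
    cycle = motion_s + static_s
    t = 0.0
    while True:
        t_on = t + static_s
        if t_on >= trial_duration:
            break
        t_off = min(t_on + motion_s, trial_duration)
        intervals.append((t_on, t_off))
        t += cycle
    return StimulusSchedule(trial_duration=trial_duration, intervals=tuple(intervals))
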
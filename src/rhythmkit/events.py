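"""Core representation of timed vocal events and inter-event intervals.

An :class:`EventSeries` is an ordered set of event onset times (call onsets,
syllable centers, envelope peaks, synthetic pulses ...) on a finite
observation window, optionally with per-event durations.  The elementary
derived quantity is the inter-event interval (IEI): the temporal duration
encompassed by two successive events.  All internal units are seconds;
milliseconds appear only at display/export time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "EventSeries",
    "IntervalSequence",
    "IntervalConvention",
    "intervals",
]


class IntervalConvention(str, Enum):
    """How an interval between successive events is measured.

    ``ONSET_TO_ONSET`` is the default: synthetic pulses are instantaneous,
    so onset-to-onset is the natural reading.  ``OFFSET_TO_ONSET`` (the
    silent gap between calls) requires per-event durations and can be
    negative when calls overlap.
    """

    ONSET_TO_ONSET = "onset-to-onset"
    OFFSET_TO_ONSET = "offset-to-onset"


def _quantize(x: np.ndarray, resolution: float) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float) / resolution) * resolution


@dataclass(frozen=True)
class EventSeries:
    """Ordered event onsets over a finite observation window.

    Parameters
    ----------
    times:
        Event onset times in seconds, strictly increasing after quantization
        to ``resolution``.
    t_start, t_end:
        Observation window; ``t_start <= times[0]`` and ``times[-1] <= t_end``.
    resolution:
        Temporal quantization of the source in seconds (e.g. ``0.001`` for a
        1-kHz annotation grid).  Times are snapped to this grid on ingest;
        ties after quantization raise rather than being silently merged.
    durations:
        Optional per-event durations (offset − onset) in seconds, all > 0.
    """

    times: np.ndarray
    t_start: float = 0.0
    t_end: Optional[float] = None
    resolution: float = 0.001
    label: str = ""
    durations: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        times = _quantize(times, self.resolution)
        if times.size and times[0] < 0:
            raise ValueError("event times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                "event times must be strictly increasing after quantization "
                f"to resolution={self.resolution}; ties are an error"
            )
        object.__setattr__(self, "times", times)
        t_end = self.t_end if self.t_end is not None else (times[-1] if times.size else 0.0)
        object.__setattr__(self, "t_end", float(t_end))
        if times.size:
            if self.t_start > times[0] + 1e-12:
                raise ValueError("t_start must not exceed the first event time")
            if times[-1] > self.t_end + 1e-12:
                raise ValueError("t_end must not precede the last event time")
        if self.durations is not None:
            durations = np.asarray(self.durations, dtype=float)
            if durations.shape != times.shape:
                raise ValueError("durations must match times in length")
            if np.any(durations <= 0):
                raise ValueError("all durations must be positive")
            object.__setattr__(self, "durations", durations)

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    @property
    def span(self) -> float:
        """Length of the observation window in seconds."""
        return float(self.t_end - self.t_start)

    def shifted(self, dt: float) -> "EventSeries":
        """Return a copy with all times (and the window) shifted by ``dt``."""
        return replace(
            self,
            times=self.times + dt,
            t_start=self.t_start + dt,
            t_end=self.t_end + dt,
        )

    def intervals(
        self, convention: IntervalConvention = IntervalConvention.ONSET_TO_ONSET
    ) -> "IntervalSequence":
        return intervals(self, convention)


@dataclass(frozen=True)
class IntervalSequence:
    """Sequence of inter-event intervals, in seconds, in production order."""

    values: np.ndarray
    convention: IntervalConvention = IntervalConvention.ONSET_TO_ONSET
    overlap_flags: Optional[np.ndarray] = field(default=None)
    label: str = ""

    def __post_init__(self) -> None:
        values = np.atleast_1d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        if self.overlap_flags is not None:
            flags = np.asarray(self.overlap_flags, dtype=bool)
            if flags.shape != values.shape:
                raise ValueError("overlap_flags must match values in length")
            object.__setattr__(self, "overlap_flags", flags)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def positive(self) -> np.ndarray:
        """Strictly positive intervals (the only ones with a defined log)."""
        return self.values[self.values > 0]


def intervals(
    events: EventSeries,
    convention: IntervalConvention | str = IntervalConvention.ONSET_TO_ONSET,
) -> IntervalSequence:
    """Derive inter-event intervals from an event series.

    Onset-to-onset: ``values[i] = times[i+1] - times[i]`` (always positive).
    Offset-to-onset: ``values[i] = times[i+1] - (times[i] + durations[i])``;
    overlapping calls yield non-positive gaps, which are *retained* but
    flagged — downstream log-IEI construction excludes them.

    Raises
    ------
    ValueError
        If the series has fewer than two events, or offset-to-onset is
        requested without durations.
    """
    convention = IntervalConvention(convention)
    if events.n_events < 2:
        raise ValueError("at least 2 events are required to form intervals")
    if convention is IntervalConvention.ONSET_TO_ONSET:
        vals = np.diff(events.times)
        return IntervalSequence(vals, convention, label=events.label)
    if events.durations is None:
        raise ValueError("offset-to-onset intervals require per-event durations")
    vals = events.times[1:] - (events.times[:-1] + events.durations[:-1])
    flags = vals <= 0
    if flags.any():
        warnings.warn(
            f"{int(flags.sum())} non-positive offset-to-onset interval(s) "
            "from overlapping calls; retained with overlap_flags set",
            stacklevel=2,
        )
    return IntervalSequence(vals, convention, overlap_flags=flags, label=events.label)
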
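"""Core containers: uniformly sampled EEG traces and seizure event lists.

Time convention: seconds from record start; sample ``i`` covers the half-open
interval ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["TimeSeries", "SeizureEvent", "EventList", "AnnotatedRecord"]


@dataclass
class TimeSeries:
    """One channel of uniformly sampled EEG.

    Parameters
    ----------
    samples : ndarray
        Voltage values in microvolts.
    fs : float
        Sampling frequency in Hz (must be positive).
    label : str
        Channel name in 10-20 nomenclature, or a bipolar derivation ``"A-B"``.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not self.fs > 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"non-finite samples in channel {self.label!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    def copy(self, samples: np.ndarray | None = None, label: str | None = None) -> "TimeSeries":
        return TimeSeries(
            samples=self.samples.copy() if samples is None else samples,
            fs=self.fs,
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class SeizureEvent:
    """A detected (or annotated) seizure interval.

    ``flags`` records the names of the detector checks the event passed
    (e.g. ``{"duration", "amplitude", "spike", "variance"}``); reference
    annotations carry an empty flag set.
    """

    start: float
    end: float
    channels: tuple[str, ...] = ()
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"event start must precede end, got [{self.start}, {self.end}]")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "SeizureEvent", margin: float = 0.0) -> bool:
        return self.start < other.end + margin and other.start < self.end + margin


class EventList:
    """Sorted list of seizure events (sorted by start time on construction)."""

    def __init__(self, events: Iterable[SeizureEvent] = ()) -> None:
        self.events: list[SeizureEvent] = sorted(events, key=lambda e: (e.start, e.end))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SeizureEvent]:
        return iter(self.events)

    def __getitem__(self, i: int) -> SeizureEvent:
        return self.events[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventList):
            return NotImplemented
        return self.events == other.events

    def __repr__(self) -> str:
        return f"EventList({self.events!r})"

    def intervals(self) -> list[tuple[float, float]]:
        return [(e.start, e.end) for e in self.events]

    @classmethod
    def from_intervals(cls, intervals: Sequence[tuple[float, float]], channels: tuple[str, ...] = ()) -> "EventList":
        return cls(SeizureEvent(s, e, channels=channels) for s, e in intervals)

    def merged(self, gap: float = 0.0) -> "EventList":
        """Merge overlapping or abutting events (gap ≤ ``gap`` seconds).

        The merged event spans earliest start to latest end; channel tuples
        are concatenated (deduplicated, order preserved) and flag sets
        intersected, so a merged event only advertises checks every
        constituent passed.
        """
        merged: list[SeizureEvent] = []
        for ev in self.events:
            if merged and ev.start <= merged[-1].end + gap:
                prev = merged[-1]
                channels = prev.channels + tuple(c for c in ev.channels if c not in prev.channels)
                merged[-1] = SeizureEvent(
                    start=prev.start,
                    end=max(prev.end, ev.end),
                    channels=channels,
                    flags=prev.flags & ev.flags if prev.flags and ev.flags else prev.flags | ev.flags,
                )
            else:
                merged.append(ev)
        return EventList(merged)


@dataclass
class AnnotatedRecord:
    """Two bipolar EEG channels plus reference seizure annotations.

    Invariants: both channels share length and sampling rate; reference
    events are sorted and disjoint.
    """

    channels: list[TimeSeries]
    reference_events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len({(len(c), c.fs) for c in self.channels}) > 1:
            raise ValueError("all channels must share length and sampling rate")
        self.reference_events = sorted((float(s), float(e)) for s, e in self.reference_events)
        for (s0, e0), (s1, _) in zip(self.reference_events, self.reference_events[1:]):
            if s1 < e0:
                raise ValueError("reference events must be disjoint")
        for s, e in self.reference_events:
            if not 0 <= s < e:
                raise ValueError(f"reference event [{s}, {e}] is malformed")

    @property
    def fs(self) -> float:
        return self.channels[0].fs

    @property
    def duration(self) -> float:
        return self.channels[0].duration

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def reference_eventlist(self) -> EventList:
        return EventList.from_intervals(self.reference_events)
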
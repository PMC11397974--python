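"""Two-hour measurement protocol timeline and stream/window alignment.

Each measurement session is a fixed cycle: a 2-min forced-oscillation (FOT)
measurement, 5 min rest, a 1-min RESMON measurement, 5 min rest — 13 min per
session, with the final session ending after its RESMON measurement (8 min),
so ten sessions span 125 min.  The wearable monitor records continuously;
its data are extracted in 2-min windows co-timed with each FOT measurement
(2-min extract + 11-min pause = the 13-min session cycle).

Times in :class:`ProtocolEvent` are minutes from the protocol origin (start
of the first FOT measurement); stream timestamps are seconds from the same
origin.  Alignment windows are half-open, ``[start, end)``, so segment
lengths are exact at integer sampling rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CoverageError, InvalidArgumentError
from .streams import SensorStream

__all__ = [
    "ProtocolEvent",
    "ProtocolTimeline",
    "build_timeline",
    "inter_measurement_interval",
    "eqv_extraction_windows",
    "align_stream",
]

EVENT_KINDS = ("FOT", "RESMON", "REST", "EQV_EXTRACT")


@dataclass(frozen=True)
class ProtocolEvent:
    """One scheduled phase of the protocol, in minutes from the origin."""

    kind: str
    session_index: int  # 1-based, "Meas 1" .. "Meas N"
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise InvalidArgumentError(f"unknown event kind {self.kind!r}")
        if self.end <= self.start:
            raise InvalidArgumentError(
                f"event {self.kind} session {self.session_index}: end must exceed start"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class ProtocolTimeline:
    """Ordered schedule of all protocol events."""

    events: tuple[ProtocolEvent, ...]
    n_sessions: int
    total_duration: float  # minutes

    def of_kind(self, kind: str) -> list[ProtocolEvent]:
        return [e for e in self.events if e.kind == kind]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_sessions": self.n_sessions,
            "total_duration_min": self.total_duration,
            "events": [asdict(e) for e in self.events],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolTimeline":
        payload = json.loads(Path(path).read_text())
        events = tuple(ProtocolEvent(**e) for e in payload["events"])
        return cls(events, payload["n_sessions"], payload["total_duration_min"])


def build_timeline(
    n_sessions: int = 10,
    fot_min: float = 2.0,
    rest_min: float = 5.0,
    resmon_min: float = 1.0,
) -> ProtocolTimeline:
    """Build the session schedule FOT → rest → RESMON → rest (per session).

    The last session omits the trailing rest, so with the defaults
    (10 sessions, 2/5/1-min phases) interior sessions span 13 min, the final
    one 8 min, and the whole protocol 125 min.
    """
    if n_sessions < 1:
        raise InvalidArgumentError("n_sessions must be >= 1")
    if min(fot_min, rest_min, resmon_min) <= 0:
        raise InvalidArgumentError("all phase durations must be > 0")

    events: list[ProtocolEvent] = []
    t = 0.0
    for k in range(1, n_sessions + 1):
        events.append(ProtocolEvent("FOT", k, t, t + fot_min))
        t += fot_min
        events.append(ProtocolEvent("REST", k, t, t + rest_min))
        t += rest_min
        events.append(ProtocolEvent("RESMON", k, t, t + resmon_min))
        t += resmon_min
        if k < n_sessions:
            events.append(ProtocolEvent("REST", k, t, t + rest_min))
            t += rest_min
    return ProtocolTimeline(tuple(events), n_sessions, t)


def inter_measurement_interval(timeline: ProtocolTimeline, device: str) -> float:
    """Gap in minutes between successive measurements of one device.

    Defined as the time from the end of one FOT (or RESMON) measurement to
    the start of the next: 11 min for FOT and 12 min for RESMON under the
    default schedule.  Constant across interior sessions by construction.
    """
    if device not in ("FOT", "RESMON"):
        raise InvalidArgumentError(f"device must be 'FOT' or 'RESMON', got {device!r}")
    meas = timeline.of_kind(device)
    if len(meas) < 2:
        raise InvalidArgumentError("inter-measurement interval needs >= 2 sessions")
    gaps = [b.start - a.end for a, b in zip(meas, meas[1:])]
    if not np.allclose(gaps, gaps[0]):
        raise InvalidArgumentError("non-constant inter-measurement gaps in timeline")
    return float(gaps[0])


def eqv_extraction_windows(timeline: ProtocolTimeline) -> list[ProtocolEvent]:
    """2-min wearable-data extraction windows, one per session.

    Each window is co-timed with that session's FOT measurement, so the
    extract/pause pattern (2 min + 11 min) tiles the 13-min session cycle.
    """
    return [
        ProtocolEvent("EQV_EXTRACT", e.session_index, e.start, e.end)
        for e in timeline.of_kind("FOT")
    ]


def align_stream(
    stream: SensorStream, windows: Sequence[ProtocolEvent] | Iterable[ProtocolEvent]
) -> list[SensorStream]:
    """Cut one segment per window from a continuous stream.

    Windows are in minutes; streams in seconds.  A segment holds the samples
    with ``window.start*60 <= t < window.end*60`` and carries the window's
    session index.  Raises :class:`CoverageError` if the stream ends before
    the last window does.
    """
    windows = list(windows)
    if not windows:
        return []
    last_end_s = max(w.end for w in windows) * 60.0
    if len(stream) == 0:
        raise CoverageError(f"stream '{stream.name}' is empty")
    # last sample at t covers [t, t + 1/fs)
    covered = stream.t[-1] + 1.0 / stream.fs
    if covered < last_end_s - 1e-9:
        raise CoverageError(
            f"stream '{stream.name}' covers only {covered:.1f} s but the last "
            f"window ends at {last_end_s:.1f} s (deficit {last_end_s - covered:.1f} s)"
        )
    segments = []
    for w in sorted(windows, key=lambda w: w.start):
        seg = stream.slice_time(w.start * 60.0, w.end * 60.0)
        seg.session_index = w.session_index
        segments.append(seg)
    return segments
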
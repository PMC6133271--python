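"""Core data model for dyadic grooming event logs.

An :class:`EventLog` couples a table of observation sessions with a table of
directed grooming events recorded inside those sessions.  Times are stored
internally as non-negative integer seconds from the start of the enclosing
session — grooming was timed to the nearest observed second, so seconds are
the native resolution and integer storage avoids float drift.  Reporting
layers convert to minutes where that is the conventional unit.

Individuals are opaque string identifiers (field codes such as ``AL`` or
``WH``).  A :class:`Dyad` is the canonical unordered pair of two individuals;
it is the statistical subject of every downstream analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

__all__ = [
    "ObservationSession",
    "GroomingEvent",
    "Dyad",
    "EventLog",
    "LogValidationError",
    "read_events",
    "write_events",
    "summarize_log",
]

EVENTS_COLUMNS = ["session_id", "groomer", "recipient", "start_s", "end_s"]
SESSIONS_COLUMNS = ["session_id", "date", "start_time", "end_time"]


class LogValidationError(ValueError):
    """Raised when an event log violates a structural invariant."""


@dataclass(frozen=True)
class ObservationSession:
    """One uninterrupted observation period.

    ``start``/``end`` are clock times on ``date``; the session duration in
    minutes is derived and must be strictly positive.
    """

    session_id: str
    date: _dt.date
    start: _dt.time
    end: _dt.time

    def __post_init__(self) -> None:
        if self.duration_minutes <= 0:
            raise LogValidationError(
                f"session {self.session_id!r}: end {self.end} not after start {self.start}"
            )

    @property
    def duration_minutes(self) -> int:
        start = self.start.hour * 60 + self.start.minute
        end = self.end.hour * 60 + self.end.minute
        return end - start

    @property
    def duration_seconds(self) -> int:
        return self.duration_minutes * 60


@dataclass(frozen=True)
class GroomingEvent:
    """One directed grooming interval: ``groomer`` grooms ``recipient``.

    ``start``/``end`` are seconds from the start of the session.
    """

    session_id: str
    groomer: str
    recipient: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.groomer == self.recipient:
            raise LogValidationError(
                f"event in session {self.session_id!r}: groomer == recipient ({self.groomer!r})"
            )
        if self.end <= self.start:
            raise LogValidationError(
                f"event {self.groomer}->{self.recipient} in session {self.session_id!r}: "
                f"end {self.end} <= start {self.start}"
            )
        if self.start < 0:
            raise LogValidationError(
                f"event {self.groomer}->{self.recipient} in session {self.session_id!r}: "
                f"negative start {self.start}"
            )

    @property
    def duration(self) -> int:
        """Event length in seconds."""
        return self.end - self.start

    @property
    def dyad(self) -> "Dyad":
        return Dyad.of(self.groomer, self.recipient)


@dataclass(frozen=True, order=True)
class Dyad:
    """Canonical unordered pair of individuals (``a < b`` lexicographically)."""

    a: str
    b: str

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise LogValidationError(f"degenerate dyad {{{self.a!r}, {self.b!r}}}")
        if self.a > self.b:
            raise LogValidationError(
                f"dyad not canonical: {self.a!r} > {self.b!r}; use Dyad.of()"
            )

    @classmethod
    def of(cls, x: str, y: str) -> "Dyad":
        """Canonicalize an ordered pair; ``of(x, y) == of(y, x)``."""
        return cls(x, y) if x < y else cls(y, x)

    def __str__(self) -> str:
        return f"{self.a}-{self.b}"

    @classmethod
    def parse(cls, text: str) -> "Dyad":
        a, _, b = text.partition("-")
        return cls.of(a, b)


@dataclass
class EventLog:
    """Validated collection of sessions and the grooming events within them."""

    sessions: list[ObservationSession]
    events: list[GroomingEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen_ids: set[str] = set()
        for s in self.sessions:
            if s.session_id in seen_ids:
                raise LogValidationError(f"duplicate session_id {s.session_id!r}")
            seen_ids.add(s.session_id)
        by_id = {s.session_id: s for s in self.sessions}
        seen_rows: set[tuple] = set()
        for ev in self.events:
            sess = by_id.get(ev.session_id)
            if sess is None:
                raise LogValidationError(
                    f"event {ev.groomer}->{ev.recipient} references unknown session "
                    f"{ev.session_id!r}"
                )
            if ev.end > sess.duration_seconds:
                raise LogValidationError(
                    f"event {ev.groomer}->{ev.recipient} ends at {ev.end}s, beyond "
                    f"session {ev.session_id!r} duration {sess.duration_seconds}s"
                )
            key = (ev.session_id, ev.groomer, ev.recipient, ev.start, ev.end)
            if key in seen_rows:
                raise LogValidationError(f"duplicate event row {key}")
            seen_rows.add(key)
        # stable sort by (session, start); preserves input order within ties
        order = {s.session_id: i for i, s in enumerate(self.sessions)}
        self.events.sort(key=lambda e: (order[e.session_id], e.start))

    @property
    def session_by_id(self) -> dict[str, ObservationSession]:
        return {s.session_id: s for s in self.sessions}

    def individuals(self) -> list[str]:
        ids = {e.groomer for e in self.events} | {e.recipient for e in self.events}
        return sorted(ids)

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.session_id, e.groomer, e.recipient, e.start, e.end) for e in self.events],
            columns=EVENTS_COLUMNS,
        )

    def sessions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    s.session_id,
                    s.date.isoformat(),
                    s.start.strftime("%H:%M"),
                    s.end.strftime("%H:%M"),
                )
                for s in self.sessions
            ],
            columns=SESSIONS_COLUMNS,
        )


def _parse_clock(text: str, *, line: int, path: str) -> _dt.time:
    try:
        hh, mm = text.strip().split(":")
        return _dt.time(int(hh), int(mm))
    except Exception as exc:
        raise LogValidationError(f"{path}:{line}: bad clock time {text!r}") from exc


def read_sessions(path: Union[str, Path]) -> list[ObservationSession]:
    """Read a sessions table (``session_id,date,start_time,end_time``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = set(SESSIONS_COLUMNS) - set(df.columns)
    if missing:
        raise LogValidationError(f"{path}: missing columns {sorted(missing)}")
    sessions = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            date = _dt.date.fromisoformat(str(row.date))
        except ValueError as exc:
            raise LogValidationError(f"{path}:{i}: bad date {row.date!r}") from exc
        sessions.append(
            ObservationSession(
                session_id=str(row.session_id),
                date=date,
                start=_parse_clock(str(row.start_time), line=i, path=str(path)),
                end=_parse_clock(str(row.end_time), line=i, path=str(path)),
            )
        )
    return sessions


def read_events(path: Union[str, Path], session_path: Union[str, Path]) -> EventLog:
    """Read and validate an event log from the two CSV tables.

    Parameters
    ----------
    path
        Events CSV with header ``session_id,groomer,recipient,start_s,end_s``;
        times are integer seconds from session start.
    session_path
        Sessions CSV with header ``session_id,date,start_time,end_time``
        (HH:MM clock times).

    Returns
    -------
    EventLog
        Fully validated; events stably sorted by (session, start).
    """
    sessions = read_sessions(session_path)
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = set(EVENTS_COLUMNS) - set(df.columns)
    if missing:
        raise LogValidationError(f"{path}: missing columns {sorted(missing)}")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            start = int(row.start_s)
            end = int(row.end_s)
        except ValueError as exc:
            raise LogValidationError(
                f"{path}:{i}: non-integer seconds ({row.start_s!r}, {row.end_s!r})"
            ) from exc
        events.append(
            GroomingEvent(
                session_id=str(row.session_id),
                groomer=str(row.groomer),
                recipient=str(row.recipient),
                start=start,
                end=end,
            )
        )
    return EventLog(sessions=sessions, events=events)


def write_events(log: EventLog, path: Union[str, Path], session_path: Union[str, Path]) -> None:
    """Write the two CSV tables in the exact dialect :func:`read_events` expects."""
    log.events_frame().to_csv(path, index=False, lineterminator="\n")
    log.sessions_frame().to_csv(session_path, index=False, lineterminator="\n")


def _events_overlap(a: GroomingEvent, b: GroomingEvent) -> bool:
    return a.start < b.end and b.start < a.end


def summarize_log(log: EventLog) -> dict:
    """Dataset-level descriptive summary.

    Returns a dict with ``n_events``, ``total_observation_hours``,
    ``total_groomed_hours`` (chimpanzee-hours: summed event lengths, which can
    exceed observation hours because events run in parallel),
    ``n_active_dyads``, ``n_possible_dyads`` (k·(k−1)/2 for the k individuals
    appearing) and ``n_mutual_dyads`` (dyads with at least one pair of
    temporally overlapping opposite-direction events).
    """
    inds = log.individuals()
    k = len(inds)
    active: set[Dyad] = {e.dyad for e in log.events}
    mutual: set[Dyad] = set()
    by_key: dict[tuple, list[GroomingEvent]] = {}
    for e in log.events:
        by_key.setdefault((e.session_id, e.dyad), []).append(e)
    for (_, dyad), evs in by_key.items():
        if dyad in mutual:
            continue
        for i, x in enumerate(evs):
            for y in evs[i + 1 :]:
                if x.groomer != y.groomer and _events_overlap(x, y):
                    mutual.add(dyad)
                    break
            if dyad in mutual:
                break
    return {
        "n_events": len(log.events),
        "total_observation_hours": sum(s.duration_minutes for s in log.sessions) / 60.0,
        "total_groomed_hours": sum(e.duration for e in log.events) / 3600.0,
        "n_active_dyads": len(active),
        "n_possible_dyads": k * (k - 1) // 2,
        "n_mutual_dyads": len(mutual),
    }
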
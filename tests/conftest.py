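import datetime as dt

import numpy as np
import pytest

from deltagroom.io_model import Dyad, EventLog, GroomingEvent, ObservationSession
from deltagroom.pairing import PairedEvent


def session(session_id="S01", minutes=120, day=1):
    end = 9 * 60 + minutes
    return ObservationSession(
        session_id=session_id,
        date=dt.date(2020, 1, day),
        start=dt.time(9, 0),
        end=dt.time(end // 60, end % 60),
    )


def make_log(event_tuples, sessions=None):
    """Build an EventLog from (session_id, groomer, recipient, start, end) tuples."""
    if sessions is None:
        ids = sorted({t[0] for t in event_tuples}) or ["S01"]
        sessions = [session(sid, minutes=600, day=i + 1) for i, sid in enumerate(ids)]
    return EventLog(
        sessions=sessions,
        events=[GroomingEvent(*t) for t in event_tuples],
    )


def make_pair(
    a="AA",
    b="BB",
    X=60,
    Y=60,
    delta=10,
    session_id="S01",
    x_start=0,
    first_groomer=None,
):
    x_end = x_start + X
    y_start = x_end + delta
    return PairedEvent(
        dyad=Dyad.of(a, b),
        session_id=session_id,
        first_groomer=first_groomer or min(a, b),
        X=X,
        Y=Y,
        delta=delta,
        x_start=x_start,
        x_end=x_end,
        y_start=y_start,
        y_end=y_start + Y,
    )


def random_log(rng: np.random.Generator, n_events=None, n_individuals=4, n_sessions=2):
    """Small dense random log for oracle comparisons (events may overlap freely)."""
    if n_events is None:
        n_events = int(rng.integers(0, 41))
    sessions = [session(f"S{i + 1:02d}", minutes=30, day=i + 1) for i in range(n_sessions)]
    inds = [f"I{k}" for k in range(n_individuals)]
    events = []
    seen = set()
    for _ in range(n_events):
        sid = sessions[int(rng.integers(0, n_sessions))].session_id
        i, j = rng.choice(n_individuals, size=2, replace=False)
        start = int(rng.integers(0, 30 * 60 - 2))
        end = start + int(rng.integers(1, 200))
        end = min(end, 30 * 60)
        key = (sid, inds[i], inds[j], start, end)
        if key in seen or end <= start:
            continue
        seen.add(key)
        events.append(GroomingEvent(sid, inds[i], inds[j], start, end))
    return EventLog(sessions=sessions, events=events)


@pytest.fixture
def two_event_log():
    """One overlapping reciprocation: A->B [0,60], B->A [30,90]."""
    return make_log([("S01", "AA", "BB", 0, 60), ("S01", "BB", "AA", 30, 90)])
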
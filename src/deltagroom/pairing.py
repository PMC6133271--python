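"""Delta-scale pairing of role-reversed grooming events.

Within a session, a grooming event ``x`` (A grooms B) and a later
opposite-direction event ``y`` (B grooms A) form a reciprocation pair,
summarized by the triple ``(X, Y, Δ)``:

* ``X`` — seconds A groomed B (the first event's duration),
* ``Y`` — seconds B groomed A,
* ``Δ`` — signed gap ``y.start − x.end`` between the end of the first event
  and the start of the reply.  Negative Δ means the reply began while the
  first event was still running (mutual grooming, *within-bout*
  reciprocation); Δ ≥ 0 is *delayed* reciprocation.

Pairs never span sessions: a reply in a later session is not a reply at all,
because grooming in the unobserved gap could have settled the account.

X-selection follows the most-recent-X rule: each candidate reply pairs with
the most recent opposite-direction event starting at or before it.  By
default the matching is one-to-one (an event serves as the X of at most one
reply); set ``reuse_x`` to let one X answer several replies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .io_model import Dyad, EventLog, GroomingEvent

__all__ = [
    "Condition",
    "WITHIN_BOUT",
    "DELAYED",
    "PairedEvent",
    "PairingPolicy",
    "pair_events",
    "pair_events_bruteforce",
    "delta_summary",
    "pairs_frame",
    "write_pairs",
    "read_pairs",
]

Condition = Literal["within_bout", "delayed"]
WITHIN_BOUT: Condition = "within_bout"
DELAYED: Condition = "delayed"

PAIRS_COLUMNS = [
    "session_id",
    "dyad",
    "first_groomer",
    "X_s",
    "Y_s",
    "delta_s",
    "condition",
    "x_start_s",
    "x_end_s",
    "y_start_s",
    "y_end_s",
]


@dataclass(frozen=True)
class PairedEvent:
    """One reciprocation pair: the ``(X, Y, Δ)`` triple plus provenance."""

    dyad: Dyad
    session_id: str
    first_groomer: str
    X: int
    Y: int
    delta: int
    x_start: int
    x_end: int
    y_start: int
    y_end: int

    @property
    def condition(self) -> Condition:
        return WITHIN_BOUT if self.delta < 0 else DELAYED

    @property
    def second_groomer(self) -> str:
        return self.dyad.b if self.first_groomer == self.dyad.a else self.dyad.a


@dataclass(frozen=True)
class PairingPolicy:
    """X-selection policy.

    ``reuse_x=False`` (default) gives one-to-one matching: each reply takes
    the most recent *unclaimed* opposite-direction event, so a single
    grooming act never appears as the X of two triples.  ``merge_gap_s``
    optionally merges same-direction events of a dyad separated by at most
    that many seconds before pairing (``None`` = no merging).
    """

    reuse_x: bool = False
    merge_gap_s: Optional[int] = None


def _event_key(e: GroomingEvent) -> tuple:
    # Role convention: earlier start is the first event; ties broken by
    # earlier end, then lexicographic groomer id.
    return (e.start, e.end, e.groomer)


def _merge_same_direction(events: list[GroomingEvent], gap: int) -> list[GroomingEvent]:
    merged: list[GroomingEvent] = []
    by_dir: dict[tuple, list[GroomingEvent]] = {}
    for e in events:
        by_dir.setdefault((e.groomer, e.recipient), []).append(e)
    for (_, _), evs in by_dir.items():
        evs = sorted(evs, key=_event_key)
        cur = evs[0]
        for e in evs[1:]:
            if e.start - cur.end <= gap:
                cur = GroomingEvent(
                    cur.session_id, cur.groomer, cur.recipient, cur.start, max(cur.end, e.end)
                )
            else:
                merged.append(cur)
                cur = e
        merged.append(cur)
    return sorted(merged, key=_event_key)


def _pair_group(
    events: list[GroomingEvent], policy: PairingPolicy
) -> list[tuple[GroomingEvent, GroomingEvent]]:
    """Pair one (session, dyad) group of events, already key-sorted."""
    used: set[int] = set()
    out = []
    for j, y in enumerate(events):
        best = -1
        for i in range(j - 1, -1, -1):
            if events[i].groomer != y.groomer and (policy.reuse_x or i not in used):
                best = i
                break
        if best >= 0:
            used.add(best)
            out.append((events[best], y))
    return out


def _make_pair(x: GroomingEvent, y: GroomingEvent) -> PairedEvent:
    return PairedEvent(
        dyad=x.dyad,
        session_id=x.session_id,
        first_groomer=x.groomer,
        X=x.duration,
        Y=y.duration,
        delta=y.start - x.end,
        x_start=x.start,
        x_end=x.end,
        y_start=y.start,
        y_end=y.end,
    )


def pair_events(log: EventLog, policy: PairingPolicy = PairingPolicy()) -> list[PairedEvent]:
    """Convert an event log into ``(X, Y, Δ)`` reciprocation pairs.

    For each candidate reply ``y``, X is taken from the most recent event of
    the opposite direction within the same session and dyad that starts at or
    before ``y`` (ties on start resolved by earlier end, then groomer id).
    Under the default one-to-one policy an event claimed as X is unavailable
    to later replies, which then fall back to the most recent unclaimed one.

    Output is sorted by (session order, reply start).
    """
    groups: dict[tuple, list[GroomingEvent]] = {}
    for e in log.events:
        groups.setdefault((e.session_id, e.dyad), []).append(e)
    session_order = {s.session_id: i for i, s in enumerate(log.sessions)}
    pairs: list[PairedEvent] = []
    for (_, _), evs in groups.items():
        if policy.merge_gap_s is not None:
            evs = _merge_same_direction(evs, policy.merge_gap_s)
        evs = sorted(evs, key=_event_key)
        for x, y in _pair_group(evs, policy):
            pairs.append(_make_pair(x, y))
    pairs.sort(key=lambda p: (session_order[p.session_id], p.y_start, p.y_end, p.first_groomer))
    return pairs


def pair_events_bruteforce(
    log: EventLog, policy: PairingPolicy = PairingPolicy(), max_events: int = 50
) -> list[PairedEvent]:
    """Reference pairing by exhaustive enumeration (small logs only).

    Enumerates every ordered opposite-direction event pair in the log,
    filters to same session and dyad, then applies the most-recent-X
    selection per reply from the full candidate table.  Intended as an
    independent check of :func:`pair_events`; refuses logs above
    ``max_events`` events.
    """
    if len(log.events) > max_events:
        raise ValueError(f"brute-force pairing refused: {len(log.events)} > {max_events} events")
    if policy.merge_gap_s is not None:
        merged = []
        groups: dict[tuple, list[GroomingEvent]] = {}
        for e in log.events:
            groups.setdefault((e.session_id, e.dyad), []).append(e)
        for evs in groups.values():
            merged.extend(_merge_same_direction(evs, policy.merge_gap_s))
        events = sorted(merged, key=lambda e: (e.session_id, _event_key(e)))
    else:
        events = list(log.events)

    # full candidate table: (x, y) with same session+dyad, roles reversed,
    # x strictly earlier in the role-convention ordering
    candidates: dict[int, list[int]] = {}
    for j, y in enumerate(events):
        for i, x in enumerate(events):
            if i == j or x.session_id != y.session_id or x.dyad != y.dyad:
                continue
            if x.groomer == y.groomer:
                continue
            if _event_key(x) < _event_key(y):
                candidates.setdefault(j, []).append(i)

    session_order = {s.session_id: i for i, s in enumerate(log.sessions)}
    used: set[int] = set()
    pairs: list[PairedEvent] = []
    for j in sorted(candidates, key=lambda j: (session_order[events[j].session_id], _event_key(events[j]))):
        avail = [i for i in candidates[j] if policy.reuse_x or i not in used]
        if not avail:
            continue
        best = max(avail, key=lambda i: _event_key(events[i]))
        used.add(best)
        pairs.append(_make_pair(events[best], events[j]))
    pairs.sort(key=lambda p: (session_order[p.session_id], p.y_start, p.y_end, p.first_groomer))
    return pairs


def delta_summary(pairs: Iterable[PairedEvent], bin_width_min: float = 10.0) -> dict:
    """Range and histogram of Δ in minutes.

    Bins are ``bin_width_min`` wide, aligned to multiples of the width, and
    cover the observed range.  Raises on empty input.
    """
    deltas_min = np.array([p.delta for p in pairs], dtype=float) / 60.0
    if deltas_min.size == 0:
        raise ValueError("delta_summary: no pairs")
    lo = np.floor(deltas_min.min() / bin_width_min) * bin_width_min
    hi = np.ceil(deltas_min.max() / bin_width_min) * bin_width_min
    if hi <= lo:
        hi = lo + bin_width_min
    edges = np.arange(lo, hi + bin_width_min / 2, bin_width_min)
    counts, edges = np.histogram(deltas_min, bins=edges)
    return {
        "min_delta_min": float(deltas_min.min()),
        "max_delta_min": float(deltas_min.max()),
        "bin_edges_min": edges.tolist(),
        "counts": counts.tolist(),
    }


def pairs_frame(pairs: Iterable[PairedEvent]) -> pd.DataFrame:
    """Tabulate pairs in the ``pairs.csv`` dialect."""
    return pd.DataFrame(
        [
            (
                p.session_id,
                str(p.dyad),
                p.first_groomer,
                p.X,
                p.Y,
                p.delta,
                p.condition,
                p.x_start,
                p.x_end,
                p.y_start,
                p.y_end,
            )
            for p in pairs
        ],
        columns=PAIRS_COLUMNS,
    )


def write_pairs(pairs: Iterable[PairedEvent], path) -> None:
    pairs_frame(pairs).to_csv(path, index=False, lineterminator="\n")


def read_pairs(path) -> list[PairedEvent]:
    df = pd.read_csv(path, dtype={"session_id": str, "dyad": str, "first_groomer": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            PairedEvent(
                dyad=Dyad.parse(row.dyad),
                session_id=str(row.session_id),
                first_groomer=str(row.first_groomer),
                X=int(row.X_s),
                Y=int(row.Y_s),
                delta=int(row.delta_s),
                x_start=int(row.x_start_s),
                x_end=int(row.x_end_s),
                y_start=int(row.y_start_s),
                y_end=int(row.y_end_s),
            )
        )
    return out
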
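"""Calendar annotations and event-marker tags, synchronized to session time.

Clinicians write down real-life events in local time as a five-column table
(Date, Start, End, Text, Color); the table is parsed, validated and clipped
against the recording span so events can shade the plots and appear in
reports.  Device tags (button presses stored as Unix times) are converted
to seconds since session start.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from matplotlib.colors import CSS4_COLORS

from .empatica_io import E4Session, local_to_unix, parse_tags
from .errors import BadCalendarSchema

logger = logging.getLogger("e4physio")

__all__ = [
    "CalendarEvent",
    "read_calendar",
    "write_calendar",
    "read_tags",
    "intersect_events",
]

REQUIRED_COLUMNS = ("Date", "Start", "End", "Text", "Color")

#: accepted shading colors: the common named web colors
KNOWN_COLORS = frozenset(CSS4_COLORS)


@dataclass(frozen=True)
class CalendarEvent:
    """One annotated activity: a day, a start/end time of day, label, color."""

    date: _dt.date
    start: _dt.time
    end: _dt.time
    text: str
    color: str

    @property
    def duration(self) -> float:
        """Event length in seconds."""
        day = _dt.date(2000, 1, 1)
        return (
            _dt.datetime.combine(day, self.end) - _dt.datetime.combine(day, self.start)
        ).total_seconds()

    def start_unix(self, tz_offset: int) -> float:
        return local_to_unix(_dt.datetime.combine(self.date, self.start), tz_offset)

    def end_unix(self, tz_offset: int) -> float:
        return local_to_unix(_dt.datetime.combine(self.date, self.end), tz_offset)


def _parse_date(token: str, row: int) -> _dt.date:
    try:
        return _dt.datetime.strptime(str(token).strip(), "%d-%m-%Y").date()
    except ValueError:
        raise BadCalendarSchema(
            f"row {row}: date {token!r} is not day-month-year (dd-mm-yyyy)"
        ) from None


def _parse_time(token, row: int) -> _dt.time:
    if isinstance(token, _dt.time):
        return token
    try:
        return _dt.datetime.strptime(str(token).strip(), "%H:%M:%S").time()
    except ValueError:
        raise BadCalendarSchema(
            f"row {row}: time {token!r} is not hour:minute:second"
        ) from None


def read_calendar(path: str | Path) -> list[CalendarEvent]:
    """Read a calendar table from delimited text or a spreadsheet.

    The five columns Date (dd-mm-yyyy), Start, End (hh:mm:ss), Text and
    Color are required (case-insensitive header match; tab or comma
    delimiters are sniffed).  Events come back chronologically sorted;
    unknown color names pass through with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path, sep=None, engine="python")
    frame.columns = [str(c).strip() for c in frame.columns]
    by_lower = {c.lower(): c for c in frame.columns}
    missing = [c for c in REQUIRED_COLUMNS if c.lower() not in by_lower]
    if missing:
        raise BadCalendarSchema(f"bad calendar schema: missing columns {missing}")

    events: list[CalendarEvent] = []
    for i, rec in frame.iterrows():
        row = int(i) + 2  # 1-based with header
        date = _parse_date(rec[by_lower["date"]], row)
        start = _parse_time(rec[by_lower["start"]], row)
        end = _parse_time(rec[by_lower["end"]], row)
        if end < start:
            raise BadCalendarSchema(f"row {row}: end {end} before start {start}")
        color = str(rec[by_lower["color"]]).strip()
        if color.lower() not in KNOWN_COLORS:
            logger.warning("row %d: unknown color %r passed through", row, color)
        events.append(
            CalendarEvent(
                date=date,
                start=start,
                end=end,
                text=str(rec[by_lower["text"]]),
                color=color,
            )
        )
    events.sort(key=lambda e: (e.date, e.start))
    return events


def write_calendar(events: list[CalendarEvent], path: str | Path) -> Path:
    """Serialize events back to the five-column CSV form (round-trippable)."""
    frame = pd.DataFrame(
        {
            "Date": [e.date.strftime("%d-%m-%Y") for e in events],
            "Start": [e.start.strftime("%H:%M:%S") for e in events],
            "End": [e.end.strftime("%H:%M:%S") for e in events],
            "Text": [e.text for e in events],
            "Color": [e.color for e in events],
        }
    )
    frame.to_csv(path, index=False)
    return Path(path)


def read_tags(path: str | Path, start_unix: float) -> list[float]:
    """Event-marker times as seconds since session start.

    Non-numeric lines are skipped with a warning; a tag before the session
    start keeps its negative offset (flagged in the log) so nothing is
    silently discarded.
    """
    offsets = []
    for t in parse_tags(Path(path).read_text()):
        off = t - start_unix
        if off < 0:
            logger.warning("tag at %s precedes session start by %.1f s", t, -off)
        offsets.append(off)
    return offsets


def intersect_events(
    session: E4Session, events: list[CalendarEvent]
) -> list[tuple[CalendarEvent, tuple[float, float]]]:
    """Clip events to the session span (session-relative seconds).

    Events wholly outside the recording are dropped with a log line; the
    returned intervals are non-empty and lie within [0, session duration].
    """
    s0, s1 = session.start_unix, session.end_unix
    out: list[tuple[CalendarEvent, tuple[float, float]]] = []
    for ev in events:
        e0 = ev.start_unix(session.tz_offset)
        e1 = ev.end_unix(session.tz_offset)
        lo, hi = max(e0, s0), min(e1, s1)
        if hi <= lo:
            logger.info("calendar event %r lies outside the session, dropped", ev.text)
            continue
        out.append((ev, (lo - s0, hi - s0)))
    return out
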
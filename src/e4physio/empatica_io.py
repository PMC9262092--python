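"""Read and write wrist-wearable session archives in the Empatica E4 CSV dialect.

An archive is a zip holding one CSV per signal (``EDA.csv``, ``BVP.csv``,
``HR.csv``, ``TEMP.csv``, ``ACC.csv``), an inter-beat-interval table
(``IBI.csv``) and optionally a tags file with one Unix event time per line.
Signal CSVs carry the Unix start time (UTC seconds) in row 1 and the
sampling frequency in Hz in row 2; samples follow, one row per ``1/fs``
seconds, one column per channel.  The IBI table instead holds
``(seconds since start, interval seconds)`` pairs, with the Unix start
time in row 1.

Recordings interrupted and restarted on the same day can be merged into a
single session.  Merged streams never fabricate samples for the time the
device was off: they carry a list of recorded-gap intervals instead, and
downstream epoching skips windows that overlap a gap.
"""

from __future__ import annotations

import datetime as _dt
import logging
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import (
    BadDialect,
    BadInterval,
    NonMonotoneBeats,
    NotSameDay,
    OverlapError,
    UnreadableArchive,
)

logger = logging.getLogger("e4physio")

__all__ = [
    "SignalStream",
    "RRSeries",
    "E4Session",
    "parse_signal_csv",
    "parse_ibi_csv",
    "read_session",
    "write_session",
    "merge_same_day",
]

#: member name, channel names and unit labels for each known signal
SIGNAL_SPECS: dict[str, tuple[str, tuple[str, ...], tuple[str, ...]]] = {
    "eda": ("EDA.csv", ("eda",), ("uS",)),
    "bvp": ("BVP.csv", ("bvp",), ("raw",)),
    "hr": ("HR.csv", ("hr",), ("bpm",)),
    "temp": ("TEMP.csv", ("temp",), ("degC",)),
    "acc": ("ACC.csv", ("x", "y", "z"), ("counts", "counts", "counts")),
}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SignalStream:
    """A uniformly sampled channel bundle with a Unix start time.

    ``samples`` has one row per time step and one column per channel.  The
    timestamp of sample *i* is ``start_unix + i/fs`` for gap-free streams;
    streams produced by same-day merging additionally carry ``gaps``, a list
    of ``(gap_start_unix, gap_end_unix)`` intervals during which the device
    recorded nothing, and timestamps of samples after a gap are shifted by
    the gap duration.
    """

    start_unix: float
    fs: float
    samples: np.ndarray
    channel_names: tuple[str, ...] = ("value",)
    units: tuple[str, ...] = ("",)
    name: str = ""
    gaps: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            self.samples = self.samples.reshape(0, len(self.channel_names))
        if self.fs <= 0:
            raise BadDialect(f"bad dialect: non-positive sampling frequency {self.fs}")
        if self.samples.shape[1] != len(self.channel_names):
            raise BadDialect(
                f"bad dialect: {self.samples.shape[1]} columns for "
                f"{len(self.channel_names)} channels"
            )

    # -- basic geometry -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recorded duration in seconds (each row covers 1/fs s)."""
        return self.n_samples / self.fs

    def timestamps(self) -> np.ndarray:
        """Unix timestamp of every sample, honouring recorded gaps."""
        t = self.start_unix + np.arange(self.n_samples) / self.fs
        for gap_start, gap_end in sorted(self.gaps):
            t[t >= gap_start - 1e-9] += gap_end - gap_start
        return t

    @property
    def end_unix(self) -> float:
        """End of the covered span (last sample time + one sample period)."""
        if self.n_samples == 0:
            return self.start_unix
        return float(self.timestamps()[-1]) + 1.0 / self.fs

    @property
    def values(self) -> np.ndarray:
        """Convenience 1-D view of a single-channel stream."""
        if self.n_channels != 1:
            raise ValueError("values is defined for single-channel streams only")
        return self.samples[:, 0]

    # -- slicing ------------------------------------------------------------

    def slice_abs(self, t0: float, t1: float, rebase_to: float | None = None) -> "SignalStream":
        """Samples with timestamps in the half-open window ``[t0, t1)``.

        ``rebase_to`` sets the output's ``start_unix`` (defaults to ``t0``);
        gaps are clipped to the window.
        """
        ts = self.timestamps()
        mask = (ts >= t0 - 1e-9) & (ts < t1 - 1e-9)
        new_start = t0 if rebase_to is None else rebase_to
        shift = new_start - t0
        new_gaps = [
            (max(gs, t0) + shift, min(ge, t1) + shift)
            for gs, ge in self.gaps
            if gs < t1 and ge > t0
        ]
        return replace(
            self,
            start_unix=new_start,
            samples=self.samples[mask],
            gaps=new_gaps,
        )


@dataclass
class RRSeries:
    """Beat offsets (s since ``start_unix``) and inter-beat durations (s).

    ``accepted`` flags are all true on read and are set by the plausibility
    filter.  Gaps between consecutive offsets larger than the corresponding
    interval are legal: the device silently discards noisy beats.
    """

    start_unix: float
    beat_offsets: np.ndarray
    intervals: np.ndarray
    accepted: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_offsets = np.asarray(self.beat_offsets, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.accepted is None:
            self.accepted = np.ones(len(self.beat_offsets), dtype=bool)
        else:
            self.accepted = np.asarray(self.accepted, dtype=bool)
        if len(self.intervals) != len(self.beat_offsets):
            raise BadDialect("bad dialect: offset/interval length mismatch")
        if len(self.accepted) != len(self.beat_offsets):
            raise BadDialect("bad dialect: accepted-flag length mismatch")
        if np.any(np.diff(self.beat_offsets) <= 0):
            raise NonMonotoneBeats("non-monotone beats")
        if np.any(self.intervals <= 0):
            raise BadInterval("bad interval: non-positive duration")

    @property
    def n_beats(self) -> int:
        return len(self.beat_offsets)

    @property
    def end_unix(self) -> float:
        if self.n_beats == 0:
            return self.start_unix
        return self.start_unix + float(self.beat_offsets[-1])

    def accepted_intervals(self) -> np.ndarray:
        return self.intervals[self.accepted]

    def slice_abs(self, t0: float, t1: float, rebase_to: float | None = None) -> "RRSeries":
        """Beats whose absolute offset lies in ``[t0, t1)``, rebased."""
        abs_t = self.start_unix + self.beat_offsets
        mask = (abs_t >= t0 - 1e-9) & (abs_t < t1 - 1e-9)
        new_start = t0 if rebase_to is None else rebase_to
        return RRSeries(
            start_unix=new_start,
            beat_offsets=abs_t[mask] - new_start,
            intervals=self.intervals[mask],
            accepted=self.accepted[mask],
        )


@dataclass
class E4Session:
    """All streams, the beat series and event tags of one recording."""

    eda: SignalStream | None = None
    bvp: SignalStream | None = None
    hr: SignalStream | None = None
    temp: SignalStream | None = None
    acc: SignalStream | None = None
    ibi: RRSeries | None = None
    tags: list[float] = field(default_factory=list)
    source_names: list[str] = field(default_factory=list)
    tz_offset: int = 0  # display-timezone offset in minutes east of UTC

    def signal_streams(self) -> Iterator[tuple[str, SignalStream]]:
        for name in SIGNAL_SPECS:
            stream = getattr(self, name)
            if stream is not None:
                yield name, stream

    @property
    def start_unix(self) -> float:
        starts = [s.start_unix for _, s in self.signal_streams()]
        if self.ibi is not None:
            starts.append(self.ibi.start_unix)
        if not starts:
            raise ValueError("session has no streams")
        return min(starts)

    @property
    def end_unix(self) -> float:
        ends = [s.end_unix for _, s in self.signal_streams()]
        if self.ibi is not None:
            ends.append(self.ibi.end_unix)
        return max(ends)

    @property
    def duration(self) -> float:
        return self.end_unix - self.start_unix

    def local_day(self) -> _dt.date:
        """Calendar day of the session start in the display timezone."""
        return unix_to_local(self.start_unix, self.tz_offset).date()


def unix_to_local(unix: float, tz_offset: int) -> _dt.datetime:
    """Naive local datetime for a Unix time and a tz offset in minutes."""
    return _dt.datetime.fromtimestamp(unix + tz_offset * 60, tz=_dt.timezone.utc).replace(
        tzinfo=None
    )


def local_to_unix(when: _dt.datetime, tz_offset: int) -> float:
    """Inverse of :func:`unix_to_local`."""
    return when.replace(tzinfo=_dt.timezone.utc).timestamp() - tz_offset * 60


# ---------------------------------------------------------------------------
# CSV parsing


def _split_rows(text: str) -> list[list[str]]:
    rows = []
    for line in text.splitlines():
        line = line.strip().lstrip("﻿")
        if line:
            rows.append([tok.strip() for tok in line.split(",")])
    return rows


def _floats(tokens: Sequence[str], context: str) -> list[float]:
    try:
        return [float(tok) for tok in tokens]
    except ValueError as exc:
        raise BadDialect(f"bad dialect in {context}: non-numeric value {exc}") from None


def parse_signal_csv(
    text: str,
    n_channels: int | None = None,
    channel_names: tuple[str, ...] | None = None,
    units: tuple[str, ...] | None = None,
    name: str = "",
) -> SignalStream:
    """Parse one signal CSV: start time row, frequency row, sample rows.

    Row 1 may repeat the start time once per channel (as the three-axis
    accelerometer file does) or give a single entry; all entries must agree.
    """
    ctx = name or "signal CSV"
    rows = _split_rows(text)
    if len(rows) < 2:
        raise BadDialect(f"bad dialect in {ctx}: missing header rows")
    starts = _floats(rows[0], ctx)
    if len(set(starts)) != 1:
        raise BadDialect(f"bad dialect in {ctx}: start-time entries disagree")
    start_unix = starts[0]
    freqs = _floats(rows[1], ctx)
    if len(set(freqs)) != 1:
        raise BadDialect(f"bad dialect in {ctx}: frequency entries disagree")
    fs = freqs[0]
    if fs <= 0:
        raise BadDialect(f"bad dialect in {ctx}: non-positive frequency {fs}")

    payload = rows[2:]
    widths = {len(r) for r in payload}
    if len(widths) > 1:
        raise BadDialect(f"bad dialect in {ctx}: ragged sample rows")
    width = widths.pop() if widths else (n_channels or len(rows[0]))
    if n_channels is not None and width != n_channels:
        raise BadDialect(f"bad dialect in {ctx}: expected {n_channels} columns, got {width}")
    samples = np.array([_floats(r, ctx) for r in payload], dtype=float).reshape(-1, width)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(width)) if width > 1 else ("value",)
    if units is None:
        units = ("",) * width
    return SignalStream(
        start_unix=start_unix,
        fs=fs,
        samples=samples,
        channel_names=channel_names,
        units=units,
        name=name,
    )


def parse_ibi_csv(text: str) -> RRSeries:
    """Parse the two-column inter-beat-interval table.

    Row 1 holds the Unix start time; a non-numeric label in its second
    column (a common dialect drift) is tolerated.  Remaining rows are
    ``(seconds since start, interval seconds)`` pairs.
    """
    rows = _split_rows(text)
    if not rows:
        raise BadDialect("bad dialect in IBI.csv: empty file")
    header = rows[0]
    start_unix = _floats(header[:1], "IBI.csv")[0]
    if len(header) > 1:
        try:
            float(header[1])
        except ValueError:
            pass  # tolerated label, e.g. "IBI"
        else:
            raise BadDialect("bad dialect in IBI.csv: numeric second header entry")
    offsets, intervals = [], []
    for row in rows[1:]:
        if len(row) != 2:
            raise BadDialect("bad dialect in IBI.csv: expected two columns")
        off, ibi = _floats(row, "IBI.csv")
        offsets.append(off)
        intervals.append(ibi)
    return RRSeries(
        start_unix=start_unix,
        beat_offsets=np.array(offsets),
        intervals=np.array(intervals),
    )


def parse_tags(text: str) -> list[float]:
    """Parse a tags file: one Unix event time per line."""
    times = []
    for i, line in enumerate(text.splitlines(), start=1):
        line = line.strip().rstrip(",")
        if not line:
            continue
        try:
            times.append(float(line.split(",")[0]))
        except ValueError:
            logger.warning("tags line %d is not numeric, skipped: %r", i, line)
    return times


# ---------------------------------------------------------------------------
# archive reading / writing


def _read_one_archive(path: Path, tz_offset: int) -> E4Session:
    try:
        zf = zipfile.ZipFile(path)
    except (FileNotFoundError, zipfile.BadZipFile, IsADirectoryError, PermissionError) as exc:
        raise UnreadableArchive(f"unreadable archive: {path} ({exc})") from None

    with zf:
        members = {Path(n).name.lower(): n for n in zf.namelist() if not n.endswith("/")}
        session = E4Session(source_names=[Path(path).stem], tz_offset=tz_offset)
        found = False
        consumed = set()
        for attr, (member, channels, units) in SIGNAL_SPECS.items():
            key = member.lower()
            if key not in members:
                continue
            text = zf.read(members[key]).decode("utf-8", errors="replace")
            try:
                stream = parse_signal_csv(
                    text, n_channels=len(channels), channel_names=channels,
                    units=units, name=member,
                )
            except BadDialect as exc:
                raise BadDialect(f"bad dialect in {path}:{member}: {exc}") from None
            setattr(session, attr, stream)
            consumed.add(key)
            found = True
        if "ibi.csv" in members:
            try:
                session.ibi = parse_ibi_csv(
                    zf.read(members["ibi.csv"]).decode("utf-8", errors="replace")
                )
            except BadDialect as exc:
                raise BadDialect(f"bad dialect in {path}:IBI.csv: {exc}") from None
            consumed.add("ibi.csv")
            found = True
        for key in ("tags.csv", "tags.txt"):
            if key in members:
                session.tags = parse_tags(zf.read(members[key]).decode("utf-8"))
                consumed.add(key)
        for key, member in members.items():
            if key not in consumed:
                logger.info("ignoring unknown archive member %s in %s", member, path)
    if not found:
        raise UnreadableArchive(f"unreadable archive: {path} contains no session CSVs")
    return session


def read_session(archive_paths: Sequence[str | Path] | str | Path, tz_offset: int = 0) -> E4Session:
    """Read one session from one or more same-day zip archives.

    Multiple archives (a device turned off and on again) are merged in
    chronological order regardless of the order given; see
    :func:`merge_same_day`.
    """
    if isinstance(archive_paths, (str, Path)):
        archive_paths = [archive_paths]
    if not archive_paths:
        raise UnreadableArchive("unreadable archive: no paths given")
    sessions = [_read_one_archive(Path(p), tz_offset) for p in archive_paths]
    if len(sessions) == 1:
        return sessions[0]
    return merge_same_day(sessions)


def _fmt(value: float) -> str:
    """Fixed-precision decimal text: integers unpadded, floats at 6 dp."""
    rounded = round(float(value), 6)
    if rounded.is_integer():
        return str(int(rounded))
    return format(rounded, ".6f")


def _stream_csv(stream: SignalStream) -> str:
    if stream.gaps:
        raise ValueError(
            "cannot serialize a stream with recorded gaps to the archive dialect"
        )
    lines = [
        ", ".join([_fmt(stream.start_unix)] * stream.n_channels),
        ", ".join([_fmt(stream.fs)] * stream.n_channels),
    ]
    for row in stream.samples:
        lines.append(", ".join(_fmt(v) for v in row))
    return "\n".join(lines) + "\n"


def _ibi_csv(series: RRSeries) -> str:
    lines = [f"{_fmt(series.start_unix)}, IBI"]
    for off, ibi in zip(series.beat_offsets, series.intervals):
        lines.append(f"{_fmt(off)}, {_fmt(ibi)}")
    return "\n".join(lines) + "\n"


def write_session(session: E4Session, path: str | Path) -> Path:
    """Write a session as a zip archive readable by :func:`read_session`.

    The round trip preserves start times, frequencies and samples at the
    fixed decimal precision of the dialect (6 decimal places).
    """
    path = Path(path)
    streams = list(session.signal_streams())
    if not streams and session.ibi is None:
        raise ValueError("session has no streams to write")
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for attr, stream in streams:
            member = SIGNAL_SPECS[attr][0]
            zf.writestr(member, _stream_csv(stream))
        if session.ibi is not None:
            zf.writestr("IBI.csv", _ibi_csv(session.ibi))
        if session.tags:
            zf.writestr("tags.csv", "\n".join(_fmt(t) for t in session.tags) + "\n")
    return path


# ---------------------------------------------------------------------------
# same-day merging


def _merge_streams(streams: list[SignalStream]) -> SignalStream:
    streams = sorted(streams, key=lambda s: s.start_unix)
    first = streams[0]
    fs = first.fs
    for s in streams[1:]:
        if s.fs != fs:
            raise BadDialect(
                f"bad dialect: sampling frequency changes across archives ({fs} vs {s.fs})"
            )
    gaps: list[tuple[float, float]] = list(first.gaps)
    samples = [first.samples]
    prev_end = first.end_unix
    for s in streams[1:]:
        if s.start_unix < prev_end - 0.5 / fs:
            raise OverlapError(
                f"overlap: recording starting {s.start_unix} overlaps previous "
                f"ending {prev_end}"
            )
        if s.start_unix > prev_end + 0.5 / fs:
            gaps.append((prev_end, s.start_unix))
        gaps.extend(s.gaps)
        samples.append(s.samples)
        prev_end = s.end_unix
    return replace(first, samples=np.vstack(samples), gaps=gaps)


def merge_same_day(sessions: Sequence[E4Session]) -> E4Session:
    """Merge sessions recorded on the same calendar day into one.

    Streams are concatenated in time order; the time the device was off is
    kept as a recorded gap, never filled with fabricated samples.  Beat
    offsets are rebased to the merged session start.  The result is
    independent of the input order.
    """
    if not sessions:
        raise ValueError("no sessions to merge")
    sessions = sorted(sessions, key=lambda s: s.start_unix)
    if len(sessions) == 1:
        return sessions[0]

    days = {s.local_day() for s in sessions}
    if len(days) > 1:
        raise NotSameDay(f"not same day: archives span {sorted(days)}")
    for prev, nxt in zip(sessions, sessions[1:]):
        if nxt.start_unix < prev.end_unix - 1e-6:
            raise OverlapError(
                f"overlap: session starting {nxt.start_unix} overlaps previous "
                f"ending {prev.end_unix}"
            )

    merged = E4Session(
        tz_offset=sessions[0].tz_offset,
        source_names=sum((s.source_names for s in sessions), []),
    )
    for name in SIGNAL_SPECS:
        present = [getattr(s, name) for s in sessions if getattr(s, name) is not None]
        if present:
            setattr(merged, name, _merge_streams(present))

    ibis = [s.ibi for s in sessions if s.ibi is not None]
    if ibis:
        merged_start = min(s.start_unix for s in sessions)
        offsets = np.concatenate(
            [ser.start_unix + ser.beat_offsets - merged_start for ser in ibis]
        )
        merged.ibi = RRSeries(
            start_unix=merged_start,
            beat_offsets=offsets,
            intervals=np.concatenate([ser.intervals for ser in ibis]),
            accepted=np.concatenate([ser.accepted for ser in ibis]),
        )
    merged.tags = sorted(t for s in sessions for t in s.tags)
    return merged


# ---------------------------------------------------------------------------
# canonical JSON dump (CLI debugging aid)


def session_to_json_dict(session: E4Session) -> dict:
    """Canonical JSON-serializable description of a session."""
    out: dict = {
        "source_names": session.source_names,
        "tz_offset": session.tz_offset,
        "start_unix": session.start_unix,
        "end_unix": session.end_unix,
        "tags": list(session.tags),
        "streams": {},
    }
    for name, stream in session.signal_streams():
        out["streams"][name] = {
            "start_unix": stream.start_unix,
            "fs": stream.fs,
            "n_samples": stream.n_samples,
            "channel_names": list(stream.channel_names),
            "units": list(stream.units),
            "gaps": [list(g) for g in stream.gaps],
        }
    if session.ibi is not None:
        out["ibi"] = {
            "start_unix": session.ibi.start_unix,
            "n_beats": session.ibi.n_beats,
        }
    return out
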
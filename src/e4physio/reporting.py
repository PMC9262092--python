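"""Display aggregation and the self-contained HTML summary report.

Sessions up to two hours plot raw; longer sessions fall back to one-minute
means so an 8-hour day renders instantly.  The report bundles the four
signal panels (EDA, heart rate, temperature, movement) with calendar
shading, optional tag lines and reference lines, the calendar table and
the interval summary table.  Every number in the summary table is taken
verbatim from the computed rows — the template never recomputes anything —
and generation is byte-deterministic given identical inputs (the embedded
timestamp is injectable).
"""

from __future__ import annotations

import html
import io
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .annotation_calendar import CalendarEvent, intersect_events
from .empatica_io import E4Session, SignalStream
from .motion_temperature import MovementConfig, acc_mean_magnitude
from .segment_and_batch import SummaryRow

__all__ = ["DisplayDefaults", "ReportOptions", "aggregate_for_display", "render_report"]

matplotlib.rcParams["svg.hashsalt"] = "e4physio"


@dataclass(frozen=True)
class DisplayDefaults:
    """Preset display ranges and aggregation rules for the four panels."""

    eda_range: tuple[float, float] = (0.0, 20.0)  # uS
    hr_range: tuple[float, float] = (40.0, 160.0)  # bpm
    temp_range: tuple[float, float] = (24.0, 38.0)  # C
    movement_range: tuple[float, float] = (0.98, 1.25)  # g
    raw_plot_max: float = 7200.0  # s: raw plotting limit (2 h)
    aggregation: float = 60.0  # s: bin width beyond the raw limit

    def __post_init__(self) -> None:
        if self.raw_plot_max <= 0 or self.aggregation <= 0:
            raise ValueError("raw_plot_max and aggregation must be positive")


@dataclass
class ReportOptions:
    title: str = "Session report"
    show_annotations: bool = True
    show_tags: bool = True
    reference_values: dict[str, float | str] = field(default_factory=dict)
    generated_at: str | None = None  # injectable for byte-stable output


def aggregate_for_display(
    stream: SignalStream,
    defaults: DisplayDefaults = DisplayDefaults(),
    session_duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Plot series for one single-channel stream (stream-relative seconds).

    Raw samples when the session fits in ``raw_plot_max``; otherwise means
    over ``aggregation``-second bins (times are bin centers).
    """
    x = stream.values
    t = stream.timestamps() - stream.start_unix
    duration = session_duration if session_duration is not None else stream.duration
    if duration <= defaults.raw_plot_max:
        return t, x
    width = defaults.aggregation
    n_bins = int(np.ceil(stream.n_samples / (width * stream.fs)))
    per_bin = int(round(width * stream.fs))
    times, means = [], []
    for k in range(n_bins):
        seg = x[k * per_bin : (k + 1) * per_bin]
        if len(seg) == 0:
            continue
        times.append(k * width + width / 2)
        means.append(seg.mean())
    return np.array(times), np.array(means)


# ---------------------------------------------------------------------------
# plotting


_PANELS = (
    ("eda", "EDA (uS)", "eda_range", "#1f77b4"),
    ("hr", "HR (bpm)", "hr_range", "#d62728"),
    ("temp", "Temperature (C)", "temp_range", "#ff7f0e"),
    ("movement", "Movement (g)", "movement_range", "#2ca02c"),
)


def _panel_streams(session: E4Session) -> dict[str, SignalStream]:
    out: dict[str, SignalStream] = {}
    if session.eda is not None:
        out["eda"] = session.eda
    if session.hr is not None:
        out["hr"] = session.hr
    if session.temp is not None:
        out["temp"] = session.temp
    if session.acc is not None:
        out["movement"] = acc_mean_magnitude(session.acc, MovementConfig())
    return out


def _figure_svg(
    session: E4Session,
    defaults: DisplayDefaults,
    options: ReportOptions,
    clipped_events: list[tuple[CalendarEvent, tuple[float, float]]],
) -> str:
    streams = _panel_streams(session)
    duration = session.duration
    fig, axes = plt.subplots(
        len(_PANELS), 1, figsize=(10, 8), sharex=True, constrained_layout=True
    )
    s0 = session.start_unix
    for ax, (key, label, range_attr, color) in zip(np.atleast_1d(axes), _PANELS):
        ax.set_ylabel(label, fontsize=8)
        ax.set_ylim(*getattr(defaults, range_attr))
        stream = streams.get(key)
        if stream is not None and stream.n_samples > 0:
            rel0 = stream.start_unix - s0
            t, y = aggregate_for_display(stream, defaults, duration)
            ax.plot((rel0 + t) / 3600.0, y, color=color, linewidth=0.7)
            ref = options.reference_values.get(key)
            if ref is not None:
                level = float(y.mean()) if ref == "mean" else float(ref)
                ax.axhline(level, color=color, linestyle="--", linewidth=0.8)
        if options.show_annotations:
            for ev, (a, b) in clipped_events:
                try:
                    ax.axvspan(a / 3600.0, b / 3600.0, color=ev.color, alpha=0.25)
                except ValueError:
                    ax.axvspan(a / 3600.0, b / 3600.0, color="0.8", alpha=0.25)
        if options.show_tags:
            for tag in session.tags:
                ax.axvline((tag - s0) / 3600.0, color="red", linewidth=0.8)
    np.atleast_1d(axes)[-1].set_xlabel("Time since session start (h)")
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# HTML assembly


def _fmt_cell(value) -> str:
    if value is None:
        return "–"
    if isinstance(value, bool):
        return "yes" if value else "no"
    if isinstance(value, float):
        return f"{value:.3f}"
    return html.escape(str(value))


_SUMMARY_COLUMNS = (
    ("start", "Start (s)"),
    ("end", "End (s)"),
    ("eda_mean", "EDA mean (uS)"),
    ("peaks_per_min", "Peaks/min"),
    ("hr_mean", "HR mean (bpm)"),
    ("rmssd", "RMSSD (ms)"),
    ("temp_mean", "Temp (C)"),
    ("movement_mean", "Movement (g)"),
    ("eda_artifact_fraction", "EDA artifact fraction"),
    ("beat_acceptance_fraction", "Beat acceptance"),
    ("movement_present", "Movement flagged"),
)


def _summary_table(summaries: list[SummaryRow]) -> str:
    head = "".join(f"<th>{html.escape(label)}</th>" for _, label in _SUMMARY_COLUMNS)
    rows = []
    for row in summaries:
        cells = "".join(
            f"<td>{_fmt_cell(getattr(row, attr))}</td>" for attr, _ in _SUMMARY_COLUMNS
        )
        rows.append(f"<tr>{cells}</tr>")
    return (
        "<table class='summary'><thead><tr>"
        + head
        + "</tr></thead><tbody>"
        + "".join(rows)
        + "</tbody></table>"
    )


def _calendar_table(events: list[CalendarEvent]) -> str:
    rows = []
    for ev in events:
        rows.append(
            "<tr>"
            f"<td>{ev.date.strftime('%d-%m-%Y')}</td>"
            f"<td>{ev.start.strftime('%H:%M:%S')}</td>"
            f"<td>{ev.end.strftime('%H:%M:%S')}</td>"
            f"<td>{html.escape(ev.text)}</td>"
            f"<td>{html.escape(ev.color)}</td>"
            "</tr>"
        )
    return (
        "<table class='calendar'><thead><tr><th>Date</th><th>Start</th>"
        "<th>End</th><th>Text</th><th>Color</th></tr></thead><tbody>"
        + "".join(rows)
        + "</tbody></table>"
    )


_STYLE = """
body { font-family: sans-serif; margin: 2em; color: #222; }
h1 { font-size: 1.4em; } h2 { font-size: 1.1em; margin-top: 1.5em; }
table { border-collapse: collapse; font-size: 0.85em; }
th, td { border: 1px solid #bbb; padding: 0.3em 0.6em; text-align: right; }
th { background: #eee; }
.notice { color: #777; font-style: italic; }
"""


def render_report(
    session: E4Session,
    summaries: list[SummaryRow] | None = None,
    events: list[CalendarEvent] | None = None,
    tags: list[float] | None = None,
    defaults: DisplayDefaults = DisplayDefaults(),
    options: ReportOptions | None = None,
) -> str:
    """Render the self-contained HTML report; returns the document text.

    Sections with no data are replaced by a short notice rather than
    omitted silently.  ``tags`` (session-relative seconds) override the
    session's own tag list when given.
    """
    options = options or ReportOptions()
    events = events or []
    if tags is not None:
        session_tags = [session.start_unix + t for t in tags]
        session = _with_tags(session, session_tags)
    clipped = intersect_events(session, events) if events else []
    svg = _figure_svg(session, defaults, options, clipped)

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>{html.escape(options.title)}</title>",
        f"<style>{_STYLE}</style></head><body>",
        f"<h1>{html.escape(options.title)}</h1>",
    ]
    if options.generated_at:
        parts.append(f"<p class='notice'>Generated {html.escape(options.generated_at)}</p>")
    parts.append(f"<p>Session of {session.duration / 3600.0:.2f} h</p>")
    parts.append("<h2>Signals</h2>")
    parts.append(svg)
    parts.append("<h2>Calendar</h2>")
    if events:
        parts.append(_calendar_table(events))
    else:
        parts.append("<p class='notice'>No calendar uploaded.</p>")
    parts.append("<h2>Analysis summary</h2>")
    if summaries:
        parts.append(_summary_table(summaries))
    else:
        parts.append("<p class='notice'>No analysis summaries available.</p>")
    parts.append("</body></html>")
    return "".join(parts)


def _with_tags(session: E4Session, tags: list[float]) -> E4Session:
    import copy

    out = copy.copy(session)
    out.tags = tags
    return out
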
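"""Cutting sessions into fixed bins, interval summaries and batch runs.

Researchers typically analyze wearable data in fixed interval bins (e.g. a
30-minute window before an incident cut into six 5-minute bins, each an
archive the rest of the toolchain can read).  Bins are half-open
``[start, start + width)`` so no sample lands in two bins; a partial
trailing bin is dropped with a log line.

``summarize_interval`` runs the full EDA / HRV / movement / temperature
pipeline over one time window and returns the per-interval aggregation
used in reports and batch output.  ``batch_process`` maps a folder of
archives to one result container each (JSON metadata + CSV tables zipped
together), skipping and logging archives that fail.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import eda_analysis as eda
from . import hrv_analysis as hrv
from . import motion_temperature as motion
from .empatica_io import E4Session, read_session
from .errors import E4Error, NoAnalyzableData, NothingToProcess, OutOfRange

logger = logging.getLogger("e4physio")

__all__ = [
    "CutSpec",
    "SummaryRow",
    "cut_session",
    "slice_session",
    "summarize_interval",
    "batch_process",
]


@dataclass(frozen=True)
class CutSpec:
    """A session-relative timeframe and the bin width to cut it into."""

    start: float  # s from session start
    end: float
    bin_width: float  # s

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not (0 < self.bin_width <= self.end - self.start):
            raise ValueError("need 0 < bin_width <= end - start")


@dataclass
class SummaryRow:
    """Per-interval aggregation feeding reports and batch output."""

    start: float  # s from session start
    end: float
    eda_mean: float | None = None
    peaks_per_min: float | None = None
    n_peaks: int = 0
    eda_artifact_fraction: float | None = None
    hr_mean: float | None = None
    sdnn: float | None = None
    rmssd: float | None = None
    pnn50: float | None = None
    beat_acceptance_fraction: float | None = None
    n_beats_original: int = 0
    n_beats_accepted: int = 0
    temp_mean: float | None = None
    movement_mean: float | None = None
    movement_present: bool = False
    signal_stats: dict[str, motion.StreamSummary] = field(default_factory=dict)


def slice_session(session: E4Session, t0: float, t1: float) -> E4Session:
    """Sub-session covering absolute Unix times ``[t0, t1)``, rebased to t0."""
    out = E4Session(
        tz_offset=session.tz_offset,
        source_names=list(session.source_names),
    )
    for name, stream in session.signal_streams():
        setattr(out, name, stream.slice_abs(t0, t1))
    if session.ibi is not None:
        out.ibi = session.ibi.slice_abs(t0, t1)
    out.tags = [t for t in session.tags if t0 <= t < t1]
    return out


def cut_session(session: E4Session, spec: CutSpec) -> list[E4Session]:
    """Cut a timeframe into fixed-width bins, each a valid session.

    Every bin's streams are rebased so their row-1 Unix time is the bin
    start; beat offsets are rebased likewise.  ``floor(span / width)``
    bins result; any partial trailing bin is dropped with a log line.
    """
    s0 = session.start_unix
    span = session.end_unix - s0
    if spec.start < -1e-9 or spec.end > span + 1e-6:
        raise OutOfRange(
            f"out of range: [{spec.start}, {spec.end}] s not within the "
            f"{span:.1f} s session"
        )
    n_bins = int(np.floor((spec.end - spec.start) / spec.bin_width + 1e-9))
    remainder = (spec.end - spec.start) - n_bins * spec.bin_width
    if remainder > 1e-9:
        logger.info(
            "cut: dropping %.1f s partial trailing bin (%d full bins)",
            remainder, n_bins,
        )
    bins = []
    stem = session.source_names[0] if session.source_names else "session"
    for k in range(n_bins):
        a = s0 + spec.start + k * spec.bin_width
        sub = slice_session(session, a, a + spec.bin_width)
        sub.source_names = [f"{stem}_bin{k:03d}"]
        bins.append(sub)
    return bins


# ---------------------------------------------------------------------------
# interval summary


def summarize_interval(
    session: E4Session,
    start: float,
    end: float,
    eda_cfg: eda.EdaConfig = eda.EdaConfig(),
    rr_cfg: hrv.RRFilterConfig = hrv.RRFilterConfig(),
    mov_cfg: motion.MovementConfig = motion.MovementConfig(),
    model: eda.ArtifactModel | None = None,
) -> SummaryRow:
    """Run every pipeline on a session-relative window and aggregate.

    Returns mean EDA over valid samples, SCR peaks per analyzable minute,
    mean HR and RMSSD over accepted beats, mean temperature and movement,
    the EDA artifact fraction (artifact epochs / classified epochs) and the
    beat acceptance fraction.  The HRV block is flagged when the window
    overlaps detected high movement, since wrist HRV is only interpretable
    at rest.
    """
    s0 = session.start_unix
    sub = slice_session(session, s0 + start, s0 + end)
    row = SummaryRow(start=start, end=end)
    any_data = False

    if sub.eda is not None and sub.eda.n_samples > 0:
        any_data = True
        pre = eda.preprocess_eda(sub.eda, eda_cfg)
        validity = eda.apply_validity_rules(pre, eda_cfg)
        feats = eda.epoch_eda_features(pre, eda_cfg)
        labels = eda.classify_eda_artifacts(feats, eda_cfg, model)
        peaks = eda.detect_scr_peaks(pre, eda_cfg, labels, validity)
        row.n_peaks = len(peaks)
        if labels:
            n_art = sum(1 for l in labels if l.label == "artifact")
            row.eda_artifact_fraction = n_art / len(labels)
        if validity.any():
            row.eda_mean = float(pre.values[validity].mean())
        analyzed = eda.analyzable_seconds(pre, eda_cfg, labels, validity)
        if analyzed > 0:
            row.peaks_per_min = eda.peaks_per_minute(peaks, analyzed)
        row.signal_stats["eda"] = motion.summarize_stream(pre, validity) \
            if validity.any() else None

    if sub.ibi is not None and sub.ibi.n_beats > 0:
        any_data = True
        res = hrv.filter_rr(sub.ibi, rr_cfg)
        row.n_beats_original = res.n_original
        row.n_beats_accepted = res.n_accepted
        row.beat_acceptance_fraction = res.acceptance_fraction
        if res.n_accepted >= 2:
            td = hrv.hrv_time_domain(res.series)
            row.hr_mean = td.mean_hr
            row.sdnn = td.sdnn
            row.rmssd = td.rmssd
            row.pnn50 = td.pnn50

    if sub.acc is not None and sub.acc.n_samples > 0:
        any_data = True
        mag = motion.acc_mean_magnitude(sub.acc, mov_cfg)
        row.movement_mean = float(mag.values.mean())
        row.movement_present = bool(motion.flag_high_movement(mag, mov_cfg))
        row.signal_stats["movement"] = motion.summarize_stream(mag)

    if sub.temp is not None and sub.temp.n_samples > 0:
        any_data = True
        row.temp_mean = float(sub.temp.values.mean())
        row.signal_stats["temp"] = motion.summarize_stream(sub.temp)

    if sub.hr is not None and sub.hr.n_samples > 0:
        any_data = True
        row.signal_stats["hr"] = motion.summarize_stream(sub.hr)

    if not any_data:
        raise NoAnalyzableData(f"no analyzable data in [{start}, {end}] s")
    return row


# ---------------------------------------------------------------------------
# batch processing


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _peaks_frame(peaks: list[eda.ScrPeak]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in peaks])


def _process_one(
    archive: Path,
    output_dir: Path,
    tz_offset: int,
    eda_cfg: eda.EdaConfig,
    rr_cfg: hrv.RRFilterConfig,
    mov_cfg: motion.MovementConfig,
) -> Path:
    session = read_session(archive, tz_offset=tz_offset)
    duration = session.end_unix - session.start_unix
    row = summarize_interval(session, 0.0, duration, eda_cfg, rr_cfg, mov_cfg)

    tables: dict[str, pd.DataFrame] = {}
    meta: dict = {
        "source_name": archive.stem,
        "start_unix": session.start_unix,
        "duration": duration,
        "summary": _jsonable(row),
    }
    if session.eda is not None and session.eda.n_samples > 0:
        pre = eda.preprocess_eda(session.eda, eda_cfg)
        validity = eda.apply_validity_rules(pre, eda_cfg)
        feats = eda.epoch_eda_features(pre, eda_cfg)
        labels = eda.classify_eda_artifacts(feats, eda_cfg)
        peaks = eda.detect_scr_peaks(pre, eda_cfg, labels, validity)
        tables["eda_processed.csv"] = pd.DataFrame({"eda": pre.values})
        tables["epoch_labels.csv"] = pd.DataFrame(
            [{"epoch_index": l.epoch_index, "label": l.label} for l in labels]
        )
        tables["peaks.csv"] = _peaks_frame(peaks)
    if session.ibi is not None and session.ibi.n_beats > 0:
        res = hrv.filter_rr(session.ibi, rr_cfg)
        tables["ibi_filtered.csv"] = pd.DataFrame(
            {
                "beat_offset": res.series.beat_offsets,
                "interval": res.series.intervals,
                "accepted": res.series.accepted.astype(int),
            }
        )
        meta["rr_filter"] = {
            "n_original": res.n_original,
            "n_accepted": res.n_accepted,
        }

    out_path = output_dir / f"{archive.stem}_results.zip"
    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("summary.json", json.dumps(meta, indent=2))
        for name, frame in tables.items():
            zf.writestr(name, frame.to_csv(index=False))
    return out_path


def batch_process(
    input_dir: str | Path,
    output_dir: str | Path,
    tz_offset: int = 0,
    eda_cfg: eda.EdaConfig = eda.EdaConfig(),
    rr_cfg: hrv.RRFilterConfig = hrv.RRFilterConfig(),
    mov_cfg: motion.MovementConfig = motion.MovementConfig(),
) -> list[Path]:
    """Process every archive in a folder into a result container.

    Each output inherits the archive's stem.  A failure on one archive is
    logged and recorded in the run manifest, never fatal to the rest.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    archives = sorted(input_dir.glob("*.zip"))
    if not archives:
        raise NothingToProcess(f"nothing to process: no archives in {input_dir}")
    output_dir.mkdir(parents=True, exist_ok=True)

    results: list[Path] = []
    manifest: dict = {"succeeded": [], "failed": []}
    for archive in archives:
        try:
            out = _process_one(archive, output_dir, tz_offset, eda_cfg, rr_cfg, mov_cfg)
        except (E4Error, OSError, ValueError) as exc:
            logger.error("batch: %s failed: %s", archive.name, exc)
            manifest["failed"].append({"archive": archive.name, "error": str(exc)})
            continue
        manifest["succeeded"].append({"archive": archive.name, "result": out.name})
        results.append(out)
    (output_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
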
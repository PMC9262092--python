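"""Synthetic session generator with ground truth, in the exact archive dialect.

Every detector in the package is testable without any recording: the
generator emits a full archive (EDA 4 Hz, BVP 64 Hz placeholder, HR 1 Hz,
TEMP and ACC 32 Hz, two-column IBI, optional tags) together with a JSON
sidecar listing the injected ground truth — SCR events, artifact epochs,
RR anomalies and movement bursts.

The SCR kernel is a linear rise to the amplitude followed by an
exponential decay: simple, closed-form, and geometrically faithful enough
to score onset/apex/amplitude recovery exactly.  The BVP channel is a sum
of harmonics at the beat rate only — a placeholder, since beat detection
from raw PPG is a vendor algorithm and out of scope.

Defaults describe a quiet resting recording: tonic level 2 uS, sensor
noise 0.0005 uS (below the ~900 pS device resolution), 60 bpm with 20 ms
beat-to-beat jitter, wrist skin temperature 33 C, and the watch at rest
(1 g on the z axis).  All randomness derives from ``spec.seed``; equal
specs generate identical archives on any platform.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .empatica_io import E4Session, RRSeries, SignalStream, write_session
from .errors import EventsTooClose

__all__ = [
    "ScrEvent",
    "ArtifactEpoch",
    "RRAnomaly",
    "MovementBurst",
    "SynthSpec",
    "synth_scr_train",
    "synth_rr_series",
    "synth_session",
    "synth_session_zip",
]


@dataclass(frozen=True)
class ScrEvent:
    """One injected skin-conductance response."""

    time: float  # onset, s from stream start
    amplitude: float  # uS
    rise: float = 2.0  # s, linear rise
    decay: float = 4.0  # s, exponential decay constant


@dataclass(frozen=True)
class ArtifactEpoch:
    """An epoch index to corrupt and how."""

    index: int
    kind: Literal["step", "dropout", "spike"] = "spike"


@dataclass(frozen=True)
class RRAnomaly:
    """A beat-series defect: a missed beat or an ectopic short interval."""

    index: int
    kind: Literal["missed", "ectopic-short"] = "missed"


@dataclass(frozen=True)
class MovementBurst:
    start: float  # s
    end: float  # s
    mean_g: float = 1.2


@dataclass(frozen=True)
class SynthSpec:
    """Conditions of one synthetic recording (all randomness from ``seed``)."""

    duration: float = 3600.0  # s
    seed: int = 0
    scr_events: tuple[ScrEvent, ...] = ()
    baseline_eda: float = 2.0  # uS tonic level
    eda_noise_sd: float = 0.0005  # uS, below the ~0.0009 uS quantization step
    artifact_epochs: tuple[ArtifactEpoch, ...] = ()
    mean_hr: float = 60.0  # bpm
    hr_jitter_sd: float = 20.0  # ms
    rr_anomalies: tuple[RRAnomaly, ...] = ()
    movement_bursts: tuple[MovementBurst, ...] = ()
    temp_baseline: float = 33.0  # C
    tags_at: tuple[float, ...] = ()  # s from start
    start_unix: float = 1581000000.0
    eda_fs: float = 4.0
    epoch_len: float = 5.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if any(e.amplitude <= 0 for e in self.scr_events):
            raise ValueError("SCR amplitudes must be positive")
        if not (0 < self.mean_hr < 300):
            raise ValueError("mean_hr must lie in (0, 300) bpm")


def _rng(spec: SynthSpec, component: int) -> np.random.Generator:
    # independent, platform-stable substream per signal component
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), component]))


# ---------------------------------------------------------------------------
# EDA


def synth_scr_train(spec: SynthSpec) -> tuple[SignalStream, list[dict]]:
    """EDA stream = baseline + SCR kernels + noise, with ground-truth peaks.

    Events must be separated by more than ``rise + 3 x decay`` of the
    earlier event so each response resolves before the next begins.
    """
    events = sorted(spec.scr_events, key=lambda e: e.time)
    for a, b in zip(events, events[1:]):
        if b.time <= a.time + a.rise + 3 * a.decay:
            raise EventsTooClose(
                f"events too close: {b.time} s follows {a.time} s within "
                f"rise + 3 x decay"
            )
    fs = spec.eda_fs
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    x = np.full(n, spec.baseline_eda, dtype=float)
    truth: list[dict] = []
    for ev in events:
        rel = t - ev.time
        rising = (rel >= 0) & (rel < ev.rise)
        decaying = rel >= ev.rise
        x[rising] += ev.amplitude * rel[rising] / ev.rise
        x[decaying] += ev.amplitude * np.exp(-(rel[decaying] - ev.rise) / ev.decay)
        truth.append(
            {
                "start": ev.time,
                "apex": ev.time + ev.rise,
                "amplitude": ev.amplitude,
                "rise": ev.rise,
                "decay": ev.decay,
            }
        )
    if spec.eda_noise_sd > 0:
        x = x + _rng(spec, 1).normal(0.0, spec.eda_noise_sd, size=n)
    stream = SignalStream(
        start_unix=spec.start_unix,
        fs=fs,
        samples=x.reshape(-1, 1),
        channel_names=("eda",),
        units=("uS",),
        name="EDA.csv",
    )
    return stream, truth


def _inject_artifacts(x: np.ndarray, spec: SynthSpec) -> np.ndarray:
    """Corrupt the chosen epochs; transitions sit strictly inside the epoch."""
    fs = spec.eda_fs
    ep = int(round(spec.epoch_len * fs))
    x = x.copy()
    for art in spec.artifact_epochs:
        i0 = art.index * ep
        if i0 >= len(x):
            raise ValueError(f"artifact epoch {art.index} beyond stream end")
        a, b = i0 + int(1 * fs), min(i0 + int(4 * fs), len(x))
        if art.kind == "step":
            x[a:b] += 10.0
        elif art.kind == "dropout":
            x[a:b] = 0.0
        elif art.kind == "spike":
            x[min(i0 + int(2.5 * fs), len(x) - 1)] += 20.0
        else:
            raise ValueError(f"unknown artifact kind {art.kind!r}")
    return x


# ---------------------------------------------------------------------------
# beats


def synth_rr_series(spec: SynthSpec) -> tuple[RRSeries, list[dict]]:
    """Plausible RR series with optional injected anomalies.

    Intervals are 60/mean_hr plus Gaussian jitter; a "missed" anomaly
    replaces two consecutive intervals with their sum (the device skipped a
    beat), "ectopic-short" halves one interval.
    """
    base = 60.0 / spec.mean_hr
    n = int(np.ceil(spec.duration / base)) + 1
    jitter = _rng(spec, 2).normal(0.0, spec.hr_jitter_sd / 1000.0, size=n)
    intervals = np.clip(base + jitter, 0.2, None)

    truth: list[dict] = []
    ivs = list(intervals)
    for anom in sorted(spec.rr_anomalies, key=lambda a: -a.index):
        i = anom.index
        if anom.kind == "missed":
            if i + 1 >= len(ivs):
                raise ValueError(f"missed-beat anomaly at {i} beyond series end")
            ivs[i] = ivs[i] + ivs[i + 1]
            del ivs[i + 1]
        elif anom.kind == "ectopic-short":
            if i >= len(ivs):
                raise ValueError(f"ectopic anomaly at {i} beyond series end")
            ivs[i] = ivs[i] / 2.0
        else:
            raise ValueError(f"unknown anomaly kind {anom.kind!r}")
        truth.append({"index": i, "kind": anom.kind})

    intervals = np.array(ivs)
    offsets = np.cumsum(intervals)
    keep = offsets <= spec.duration
    series = RRSeries(
        start_unix=spec.start_unix,
        beat_offsets=offsets[keep],
        intervals=intervals[keep],
    )
    return series, truth


# ---------------------------------------------------------------------------
# full session


def _hr_stream(spec: SynthSpec, rr: RRSeries) -> SignalStream:
    grid = np.arange(int(spec.duration))
    hr = np.interp(grid, rr.beat_offsets, 60.0 / rr.intervals)
    return SignalStream(
        start_unix=spec.start_unix, fs=1.0, samples=hr.reshape(-1, 1),
        channel_names=("hr",), units=("bpm",), name="HR.csv",
    )


def _bvp_stream(spec: SynthSpec) -> SignalStream:
    fs = 64.0
    t = np.arange(int(round(spec.duration * fs))) / fs
    f0 = spec.mean_hr / 60.0
    x = 0.5 * np.sin(2 * np.pi * f0 * t) + 0.2 * np.sin(4 * np.pi * f0 * t)
    return SignalStream(
        start_unix=spec.start_unix, fs=fs, samples=x.reshape(-1, 1),
        channel_names=("bvp",), units=("raw",), name="BVP.csv",
    )


def _temp_stream(spec: SynthSpec) -> SignalStream:
    fs = 32.0
    t = np.arange(int(round(spec.duration * fs))) / fs
    x = spec.temp_baseline + 0.3 * np.sin(2 * np.pi * t / 1800.0)
    x = np.round(x / 0.02) * 0.02  # sensor resolution 0.02 C
    return SignalStream(
        start_unix=spec.start_unix, fs=fs, samples=x.reshape(-1, 1),
        channel_names=("temp",), units=("degC",), name="TEMP.csv",
    )


def _acc_stream(spec: SynthSpec) -> SignalStream:
    fs = 32.0
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    counts = np.zeros((n, 3))
    counts[:, 2] = 64.0  # at rest: 1 g on z
    counts += _rng(spec, 3).integers(-1, 2, size=(n, 3))
    for burst in spec.movement_bursts:
        mask = (t >= burst.start) & (t < burst.end)
        counts[mask, 2] = np.round(burst.mean_g * 64.0)
    return SignalStream(
        start_unix=spec.start_unix, fs=fs, samples=counts,
        channel_names=("x", "y", "z"), units=("counts",) * 3, name="ACC.csv",
    )


def synth_session(spec: SynthSpec = SynthSpec()) -> tuple[E4Session, dict]:
    """Build a full in-memory session plus its ground-truth record."""
    eda, scr_truth = synth_scr_train(spec)
    eda_x = _inject_artifacts(eda.values, spec)
    eda = SignalStream(
        start_unix=eda.start_unix, fs=eda.fs, samples=eda_x.reshape(-1, 1),
        channel_names=eda.channel_names, units=eda.units, name=eda.name,
    )
    rr, rr_truth = synth_rr_series(spec)
    session = E4Session(
        eda=eda,
        bvp=_bvp_stream(spec),
        hr=_hr_stream(spec, rr),
        temp=_temp_stream(spec),
        acc=_acc_stream(spec),
        ibi=rr,
        tags=[spec.start_unix + t for t in spec.tags_at],
        source_names=["synthetic"],
    )
    truth = {
        "spec": asdict(spec),
        "scr_peaks": scr_truth,
        "artifact_epochs": [asdict(a) for a in spec.artifact_epochs],
        "rr_anomalies": rr_truth,
        "movement_bursts": [asdict(b) for b in spec.movement_bursts],
    }
    return session, truth


def synth_session_zip(
    spec: SynthSpec, path: str | Path
) -> tuple[Path, Path]:
    """Write the archive and its ground-truth sidecar; returns both paths."""
    path = Path(path)
    session, truth = synth_session(spec)
    write_session(session, path)
    sidecar = path.with_suffix(".truth.json")
    sidecar.write_text(json.dumps(truth, indent=2))
    return path, sidecar
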
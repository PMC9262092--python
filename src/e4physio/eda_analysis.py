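"""Electrodermal activity: preprocessing, artifact screening, SCR features.

The pipeline follows the common wrist-EDA recipe: the 4 Hz skin-conductance
signal is upsampled to 8 Hz and low-pass filtered (SCR energy lives below
~1 Hz); 5-s epochs are classified as artifact / unclear / clean from
epoch statistics and short-scale wavelet detail coefficients; samples
outside the device's measurable range (0.01-100 uS) are masked; and
skin-conductance responses (SCRs) are detected as rise-and-decay peaks, each
characterized by its onset level, amplitude, rise time, maximum derivative,
decay time, width and area under the curve.  Detected peaks are summarized
as peaks per minute of analyzable (valid, artifact-free) time.

The original epoch classifier is a support vector machine trained on
expert-labeled data; its weights are not public.  The classifier here is a
pluggable linear decision function over the epoch features, and the shipped
default is an explicit rule set (per-sample slope limit and epoch-range
limit) that fires on step, spike and dropout glitches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pywt
from scipy import signal as sps

from .empatica_io import SignalStream
from .errors import DownsamplingUnsupported, ModelMismatch, NoAnalyzableData

__all__ = [
    "EdaConfig",
    "EpochFeatures",
    "ArtifactLabel",
    "ScrPeak",
    "ArtifactModel",
    "RuleBasedModel",
    "LinearModel",
    "preprocess_eda",
    "epoch_eda_features",
    "classify_eda_artifacts",
    "apply_validity_rules",
    "detect_scr_peaks",
    "peaks_per_minute",
    "analyzable_seconds",
]

FEATURE_NAMES = (
    "mean",
    "max",
    "min",
    "max_abs_diff1",
    "max_abs_diff2",
    "w1s_max",
    "w1s_mean",
    "w1s_count",
    "whalf_max",
    "whalf_mean",
    "whalf_count",
)


@dataclass(frozen=True)
class EdaConfig:
    """Tunable parameters of the EDA pipeline.

    target_fs : Hz the signal is upsampled to before filtering.
    filter_cutoff / filter_taps : zero-phase FIR low-pass design.
    epoch_len : artifact-classification window, seconds.
    peak_amplitude_threshold : minimum SCR amplitude in uS.
    valid_min / valid_max : measurable skin-conductance range in uS.
    """

    target_fs: float = 8.0
    filter_cutoff: float = 1.0
    filter_taps: int = 33
    epoch_len: float = 5.0
    peak_amplitude_threshold: float = 0.005
    classifier_mode: Literal["binary", "ternary"] = "binary"
    valid_min: float = 0.01
    valid_max: float = 100.0
    wavelet: str = "haar"
    wavelet_count_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")
        if not (0 <= self.valid_min < self.valid_max):
            raise ValueError("need 0 <= valid_min < valid_max")
        if self.peak_amplitude_threshold <= 0:
            raise ValueError("peak_amplitude_threshold must be positive")
        if self.classifier_mode not in ("binary", "ternary"):
            raise ValueError("classifier_mode must be 'binary' or 'ternary'")


@dataclass(frozen=True)
class EpochFeatures:
    """Statistics of one 5-s epoch of the preprocessed signal.

    Raw-epoch statistics (mean/max/min, max absolute first and second
    difference) plus, for the one-second and half-second wavelet detail
    scales: max and mean absolute coefficient and the count of coefficients
    above a small threshold.
    """

    epoch_index: int
    mean: float
    max: float
    min: float
    max_abs_diff1: float
    max_abs_diff2: float
    w1s_max: float
    w1s_mean: float
    w1s_count: float
    whalf_max: float
    whalf_mean: float
    whalf_count: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


@dataclass(frozen=True)
class ArtifactLabel:
    epoch_index: int
    label: Literal["clean", "unclear", "artifact"]


@dataclass(frozen=True)
class ScrPeak:
    """One detected skin-conductance response.

    Times are seconds relative to the stream start.  ``half_recovery_time``
    (and the quantities derived from it: decay time, width, AUC) are absent
    when the signal does not fall back to half amplitude before the next
    peak begins.
    """

    start_time: float
    apex_time: float
    eda_at_start: float
    amplitude: float
    rise_time: float
    max_derivative: float
    half_recovery_time: float | None = None
    decay_time: float | None = None
    width: float | None = None
    auc: float | None = None


# ---------------------------------------------------------------------------
# preprocessing


def _fir_lowpass(cfg: EdaConfig) -> np.ndarray:
    return sps.firwin(
        cfg.filter_taps, cfg.filter_cutoff, fs=cfg.target_fs, window="hamming"
    )


def _upsample_filter_segment(x: np.ndarray, fs: float, cfg: EdaConfig) -> np.ndarray:
    n_out = int(round(len(x) * cfg.target_fs / fs))
    if len(x) == 0:
        return x
    t_in = np.arange(len(x)) / fs
    t_out = np.arange(n_out) / cfg.target_fs
    y = np.interp(t_out, t_in, x)  # linear: monotone, no fabricated overshoot
    if len(y) > 3:
        taps = _fir_lowpass(cfg)
        padlen = min(3 * (len(taps) - 1), len(y) - 1)
        y = sps.filtfilt(taps, [1.0], y, padlen=padlen)
    return y


def preprocess_eda(stream: SignalStream, cfg: EdaConfig = EdaConfig()) -> SignalStream:
    """Upsample a skin-conductance stream to ``cfg.target_fs`` and low-pass it.

    The FIR filter is applied forward-backward (zero phase) so SCR rise and
    decay timing is not biased.  Output duration equals input duration.
    Streams with recorded gaps are processed per contiguous segment.
    """
    if stream.n_channels != 1:
        raise ValueError("preprocess_eda expects a single-channel stream")
    if stream.fs > cfg.target_fs:
        raise DownsamplingUnsupported(
            f"downsampling unsupported: input fs {stream.fs} > target {cfg.target_fs}"
        )
    x = stream.values
    if stream.gaps:
        ts = stream.timestamps()
        bounds = sorted(stream.gaps)
        pieces, i0 = [], 0
        for gs, _ge in bounds:
            i1 = int(np.searchsorted(ts, gs - 1e-9))
            pieces.append(_upsample_filter_segment(x[i0:i1], stream.fs, cfg))
            i0 = i1
        pieces.append(_upsample_filter_segment(x[i0:], stream.fs, cfg))
        y = np.concatenate(pieces)
    else:
        y = _upsample_filter_segment(x, stream.fs, cfg)
    return replace(
        stream,
        fs=cfg.target_fs,
        samples=y.reshape(-1, 1),
        gaps=list(stream.gaps),
    )


# ---------------------------------------------------------------------------
# epoch features


def _detail_coeffs(x: np.ndarray, fs: float, scale_s: float, wavelet: str) -> np.ndarray:
    """One-level wavelet detail coefficients at a given time scale.

    The decomposition level is chosen so a detail coefficient spans
    ``scale_s`` seconds at the stream's sampling rate (e.g. level 3 for the
    1-s scale at 8 Hz).
    """
    level = max(1, int(round(np.log2(fs * scale_s))))
    if len(x) < 2**level:
        return np.zeros(1)
    coeffs = pywt.wavedec(x, wavelet, level=level)
    return coeffs[1]  # detail at the coarsest requested scale


def epoch_eda_features(
    stream: SignalStream, cfg: EdaConfig = EdaConfig()
) -> list[EpochFeatures]:
    """Features of every complete epoch; partial and gap-overlapping epochs drop."""
    if stream.n_channels != 1:
        raise ValueError("epoch_eda_features expects a single-channel stream")
    x = stream.values
    fs = stream.fs
    ep_n = int(round(cfg.epoch_len * fs))
    n_epochs = len(x) // ep_n
    if n_epochs == 0:
        return []
    ts = stream.timestamps() if stream.gaps else None
    feats: list[EpochFeatures] = []
    for k in range(n_epochs):
        seg = x[k * ep_n : (k + 1) * ep_n]
        if ts is not None:
            t0, t1 = ts[k * ep_n], ts[(k + 1) * ep_n - 1] + 1.0 / fs
            if any(gs < t1 and ge > t0 for gs, ge in stream.gaps):
                continue
        d1 = np.abs(np.diff(seg)) if len(seg) > 1 else np.zeros(1)
        d2 = np.abs(np.diff(seg, n=2)) if len(seg) > 2 else np.zeros(1)
        w1 = np.abs(_detail_coeffs(seg, fs, 1.0, cfg.wavelet))
        wh = np.abs(_detail_coeffs(seg, fs, 0.5, cfg.wavelet))
        feats.append(
            EpochFeatures(
                epoch_index=k,
                mean=float(seg.mean()),
                max=float(seg.max()),
                min=float(seg.min()),
                max_abs_diff1=float(d1.max()),
                max_abs_diff2=float(d2.max()),
                w1s_max=float(w1.max()),
                w1s_mean=float(w1.mean()),
                w1s_count=float((w1 > cfg.wavelet_count_threshold).sum()),
                whalf_max=float(wh.max()),
                whalf_mean=float(wh.mean()),
                whalf_count=float((wh > cfg.wavelet_count_threshold).sum()),
            )
        )
    return feats


# ---------------------------------------------------------------------------
# artifact classification


class ArtifactModel:
    """Interface of an epoch classifier: score >= 1 means artifact."""

    def score(self, features: EpochFeatures, cfg: EdaConfig) -> float:
        raise NotImplementedError


@dataclass(frozen=True)
class RuleBasedModel(ArtifactModel):
    """Default rule set standing in for the unpublished trained classifier.

    An epoch is an artifact when the per-sample slope exceeds
    ``slope_limit`` uS/s, or the epoch's range exceeds ``range_fraction`` of
    the device's measurable range (a swing that large within 5 s is not
    physiological).  The score is the worst rule ratio, so values just
    below 1 form the ternary "unclear" band.
    """

    slope_limit: float = 10.0  # uS/s
    range_fraction: float = 0.2
    unclear_band: float = 0.75  # ternary: score in [unclear_band, 1) -> unclear

    def score(self, features: EpochFeatures, cfg: EdaConfig) -> float:
        range_limit = self.range_fraction * (cfg.valid_max - cfg.valid_min)
        slope = features.max_abs_diff1 * cfg.target_fs
        ep_range = features.max - features.min
        return max(slope / self.slope_limit, ep_range / range_limit)

    @property
    def unclear_threshold(self) -> float:
        return self.unclear_band


class AlwaysCleanModel(ArtifactModel):
    """Scores every epoch 0; reduces peak detection to unmasked detection."""

    def score(self, features: EpochFeatures, cfg: EdaConfig) -> float:
        return 0.0


@dataclass(frozen=True)
class LinearModel(ArtifactModel):
    """Linear decision function over named epoch features.

    ``score = (w . f + bias)``; the epoch is an artifact when the score is
    >= 1 and, in ternary mode, "unclear" within ``margin`` below 1.
    """

    weights: dict[str, float]
    bias: float = 0.0
    margin: float = 0.25

    def score(self, features: EpochFeatures, cfg: EdaConfig) -> float:
        vec = features.as_dict()
        unknown = set(self.weights) - set(vec)
        if unknown:
            raise ModelMismatch(f"model mismatch: unknown features {sorted(unknown)}")
        return sum(w * vec[name] for name, w in self.weights.items()) + self.bias

    @property
    def unclear_threshold(self) -> float:
        return 1.0 - self.margin

    @classmethod
    def from_file(cls, path: str | Path) -> "LinearModel":
        data = json.loads(Path(path).read_text())
        return cls(
            weights={str(k): float(v) for k, v in data["weights"].items()},
            bias=float(data.get("bias", 0.0)),
            margin=float(data.get("margin", 0.25)),
        )


def classify_eda_artifacts(
    features: Sequence[EpochFeatures],
    cfg: EdaConfig = EdaConfig(),
    model: ArtifactModel | None = None,
) -> list[ArtifactLabel]:
    """Label each epoch clean / unclear / artifact.

    Binary mode never emits "unclear".  The decision is a score from the
    model: >= 1 is an artifact; in ternary mode a band just below 1 is
    "unclear".
    """
    if model is None:
        model = RuleBasedModel()
    unclear_thr = getattr(model, "unclear_threshold", 0.75)
    labels: list[ArtifactLabel] = []
    for f in features:
        s = model.score(f, cfg)
        if s >= 1.0:
            lab = "artifact"
        elif cfg.classifier_mode == "ternary" and s >= unclear_thr:
            lab = "unclear"
        else:
            lab = "clean"
        labels.append(ArtifactLabel(epoch_index=f.epoch_index, label=lab))
    return labels


def apply_validity_rules(
    stream: SignalStream, cfg: EdaConfig = EdaConfig()
) -> np.ndarray:
    """Per-sample validity mask: values outside [valid_min, valid_max] are out.

    Values approaching 0 are unmeasurable contact losses; values above the
    device ceiling are saturation.  Masked samples are excluded from peak
    detection and summaries.
    """
    x = stream.values
    return (x >= cfg.valid_min) & (x <= cfg.valid_max)


# ---------------------------------------------------------------------------
# SCR peak detection


def _artifact_epoch_set(labels: Sequence[ArtifactLabel] | None) -> set[int]:
    if not labels:
        return set()
    return {l.epoch_index for l in labels if l.label == "artifact"}


def detect_scr_peaks(
    stream: SignalStream,
    cfg: EdaConfig = EdaConfig(),
    labels: Sequence[ArtifactLabel] | None = None,
    validity: np.ndarray | None = None,
) -> list[ScrPeak]:
    """Detect skin-conductance responses in a preprocessed stream.

    A peak runs from the last local minimum before a rise to the next local
    maximum; its amplitude (apex minus onset level) must reach the
    configured threshold.  Peaks overlapping artifact-labeled epochs or
    invalid samples are excluded.  Half-recovery-derived features (decay
    time, width, AUC) are filled in only when the signal falls below
    onset + amplitude/2 before the next peak.
    """
    if stream.n_channels != 1:
        raise ValueError("detect_scr_peaks expects a single-channel stream")
    x = stream.values
    fs = stream.fs
    if len(x) < 3:
        return []

    # candidate apexes: local maxima with enough prominence to rule out
    # numerical ripple; plateau bookkeeping keeps flat-topped apexes exact
    apexes, props = sps.find_peaks(
        x, prominence=cfg.peak_amplitude_threshold / 2, plateau_size=(None, None)
    )
    apex_starts = props["left_edges"]  # first sample at the apex value
    minima, mprops = sps.find_peaks(-x, plateau_size=(None, None))
    # onset candidates: the last flat sample before the rise begins
    min_idx = np.concatenate(([0], mprops["right_edges"])) if len(minima) else np.array([0])

    bad_epochs = _artifact_epoch_set(labels)
    ep_n = int(round(cfg.epoch_len * fs))

    candidates: list[tuple[int, int]] = []
    for apex in apex_starts:
        before = min_idx[min_idx < apex]
        if len(before) == 0:
            continue
        start = int(before[-1])
        candidates.append((start, int(apex)))

    kept: list[tuple[int, int]] = []
    for start, apex in candidates:
        amplitude = x[apex] - x[start]
        if amplitude < cfg.peak_amplitude_threshold:
            continue
        span = slice(start, apex + 1)
        if validity is not None and not np.all(validity[span]):
            continue
        if bad_epochs and any(
            e in bad_epochs for e in range(start // ep_n, apex // ep_n + 1)
        ):
            continue
        kept.append((start, apex))

    peaks: list[ScrPeak] = []
    for i, (start, apex) in enumerate(kept):
        amplitude = float(x[apex] - x[start])
        onset = float(x[start])
        half_level = onset + amplitude / 2
        d = np.diff(x[start : apex + 1]) * fs
        max_deriv = float(d.max()) if len(d) else 0.0

        next_start = kept[i + 1][0] if i + 1 < len(kept) else len(x)
        half_idx = None
        for j in range(apex + 1, next_start):
            if x[j] < half_level:
                half_idx = j
                break

        half_time = decay = width = auc = None
        if half_idx is not None:
            half_time = half_idx / fs
            decay = (half_idx - apex) / fs
            # rising-limb half-amplitude crossing, linearly interpolated
            rise_seg = x[start : apex + 1]
            k = int(np.argmax(rise_seg >= half_level))
            k = min(max(k, 1), len(rise_seg) - 1)
            if rise_seg[k] != rise_seg[k - 1]:
                frac = (half_level - rise_seg[k - 1]) / (rise_seg[k] - rise_seg[k - 1])
            else:
                frac = 0.0
            rise_cross = (start + k - 1 + frac) / fs
            width = half_time - rise_cross
            auc = float(
                np.trapezoid(x[start : half_idx + 1] - onset) / fs
            )

        peaks.append(
            ScrPeak(
                start_time=start / fs,
                apex_time=apex / fs,
                eda_at_start=onset,
                amplitude=amplitude,
                rise_time=(apex - start) / fs,
                max_derivative=max_deriv,
                half_recovery_time=half_time,
                decay_time=decay,
                width=width,
                auc=auc,
            )
        )
    return peaks


def analyzable_seconds(
    stream: SignalStream,
    cfg: EdaConfig = EdaConfig(),
    labels: Sequence[ArtifactLabel] | None = None,
    validity: np.ndarray | None = None,
) -> float:
    """Seconds of valid, artifact-free signal (the peaks-per-minute base)."""
    n = stream.n_samples
    keep = np.ones(n, dtype=bool)
    if validity is not None:
        keep &= validity
    ep_n = int(round(cfg.epoch_len * stream.fs))
    for e in _artifact_epoch_set(labels):
        keep[e * ep_n : (e + 1) * ep_n] = False
    return float(keep.sum()) / stream.fs


def peaks_per_minute(peaks: Sequence[ScrPeak], analyzed_duration: float) -> float:
    """SCR rate per minute of analyzable time."""
    if analyzed_duration <= 0:
        raise NoAnalyzableData("no analyzable data: zero analyzed duration")
    return len(peaks) / (analyzed_duration / 60.0)
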
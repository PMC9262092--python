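"""Inter-beat-interval plausibility filtering and heart-rate variability.

Wrist PPG beat series are artifact-prone, so before any HRV statistic is
computed the RR intervals pass a physiological plausibility filter:

* resting heart rate stays between ``bpm_min`` (40) and ``bpm_max`` (180),
  so intervals outside [60/bpm_max, 60/bpm_min] seconds are suspect —
  the 40 bpm bound corresponds to a maximum RR of 1.5 s (0.67 Hz);
* over a 10-s segment the max/min RR ratio should not exceed 1.1 (heart
  rate rarely changes by more than 10% at rest);
* allowing a single missed beat doubles both allowances: a maximum RR of
  3 s and a windowed ratio bound of 2.2.

Accepted beats feed the standard time-domain measures (mean HR, SDNN,
RMSSD, pNN50) and, after interpolation onto a uniform grid, Welch spectral
band powers (VLF/LF/HF).  HRV from a wrist device is only interpretable at
rest; callers flag intervals that overlap detected movement.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .empatica_io import RRSeries, SignalStream
from .errors import InsufficientBeats, InsufficientDuration

__all__ = [
    "RRFilterConfig",
    "RRFilterResult",
    "TimeDomainHRV",
    "FreqDomainHRV",
    "DEFAULT_BANDS",
    "bpm_to_hz",
    "filter_rr",
    "rr_to_hr_series",
    "rr_to_tachogram",
    "hrv_time_domain",
    "hrv_frequency_domain",
]

#: conventional short-term HRV bands, Hz
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}


def bpm_to_hz(bpm: float) -> float:
    """Beat frequency in Hz for a heart rate in beats per minute."""
    return bpm / 60.0


@dataclass(frozen=True)
class RRFilterConfig:
    """Plausibility bounds for RR filtering.

    ``missed_beat_factor`` scales the allowances when a single missed beat
    is tolerated (factor 2: max RR 3 s, windowed ratio bound 2.2); set it
    to 1 to disable the allowance.
    """

    bpm_min: float = 40.0
    bpm_max: float = 180.0
    segment_len: float = 10.0
    ratio_max: float = 1.1
    missed_beat_factor: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.bpm_min < self.bpm_max):
            raise ValueError("need 0 < bpm_min < bpm_max")
        if self.segment_len <= 0 or self.ratio_max < 1 or self.missed_beat_factor < 1:
            raise ValueError("bad filter configuration")

    @property
    def min_rr(self) -> float:
        """Shortest plausible interval, s (60/bpm_max)."""
        return 60.0 / self.bpm_max

    @property
    def max_rr(self) -> float:
        """Longest plausible interval without a missed beat, s (60/bpm_min)."""
        return 60.0 / self.bpm_min

    @property
    def max_rr_allowed(self) -> float:
        """Longest interval once a single missed beat is allowed, s."""
        return self.missed_beat_factor * self.max_rr

    @property
    def ratio_bound_allowed(self) -> float:
        """Windowed max/min ratio bound with the missed-beat allowance."""
        return self.missed_beat_factor * self.ratio_max


@dataclass
class RRFilterResult:
    series: RRSeries
    n_original: int
    n_accepted: int

    @property
    def acceptance_fraction(self) -> float:
        if self.n_original == 0:
            return float("nan")
        return self.n_accepted / self.n_original


@dataclass(frozen=True)
class TimeDomainHRV:
    mean_hr: float  # bpm
    sdnn: float  # ms
    rmssd: float  # ms
    pnn50: float  # %


@dataclass(frozen=True)
class FreqDomainHRV:
    vlf_power: float  # ms^2
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    interpolation_fs: float
    total_power: float


# ---------------------------------------------------------------------------
# plausibility filter


def _window_members(offsets: np.ndarray, accepted: np.ndarray, i: int, seg: float) -> np.ndarray:
    """Indices of accepted beats in the window anchored at accepted beat i."""
    lo, hi = offsets[i], offsets[i] + seg
    idx = np.where(accepted & (offsets >= lo) & (offsets <= hi))[0]
    return idx


def _ratio_pass(offsets: np.ndarray, intervals: np.ndarray, accepted: np.ndarray,
                cfg: RRFilterConfig) -> bool:
    """One sweep of the windowed max/min ratio rule; True if anything changed.

    The later beat of the offending (max, min) pair is rejected first, then
    the window is re-evaluated.
    """
    changed = False
    bound = cfg.ratio_bound_allowed
    for i in range(len(offsets)):
        if not accepted[i]:
            continue
        while True:
            idx = _window_members(offsets, accepted, i, cfg.segment_len)
            if len(idx) < 2:
                break
            vals = intervals[idx]
            if vals.max() / vals.min() <= bound:
                break
            offender = max(idx[np.argmax(vals)], idx[np.argmin(vals)])
            accepted[offender] = False
            changed = True
    return changed


def _single_interval_pass(offsets: np.ndarray, intervals: np.ndarray,
                          accepted: np.ndarray, cfg: RRFilterConfig) -> bool:
    """Reject long intervals whose local window ratio also breaks the 10% rule."""
    changed = False
    for i in range(len(offsets)):
        if not accepted[i] or intervals[i] <= cfg.max_rr:
            continue
        lo = offsets[i] - cfg.segment_len / 2
        hi = offsets[i] + cfg.segment_len / 2
        idx = np.where(accepted & (offsets >= lo) & (offsets <= hi))[0]
        vals = intervals[idx]
        if len(vals) >= 2 and vals.max() / vals.min() > cfg.ratio_max:
            accepted[i] = False
            changed = True
    return changed


def filter_rr(series: RRSeries, cfg: RRFilterConfig = RRFilterConfig()) -> RRFilterResult:
    """Apply the plausibility rules; returns accepted-vs-original counts.

    Rules, in order: (1) hard interval bounds — shorter than 60/bpm_max or
    longer than the missed-beat-allowed maximum; (2) windowed max/min ratio
    over each ``segment_len`` window, bound ``missed_beat_factor x
    ratio_max``; (3) a single interval above 60/bpm_min whose local window
    ratio also exceeds ``ratio_max``.  Passes 2-3 repeat to a fixpoint, so
    the filter is idempotent.
    """
    n = series.n_beats
    if n == 0:
        return RRFilterResult(series=series, n_original=0, n_accepted=0)
    offsets = series.beat_offsets
    intervals = series.intervals
    accepted = series.accepted.copy()

    accepted &= intervals >= cfg.min_rr
    accepted &= intervals <= cfg.max_rr_allowed

    while True:
        changed = _ratio_pass(offsets, intervals, accepted, cfg)
        changed |= _single_interval_pass(offsets, intervals, accepted, cfg)
        if not changed:
            break

    out = replace(series, accepted=accepted)
    return RRFilterResult(series=out, n_original=n, n_accepted=int(accepted.sum()))


# ---------------------------------------------------------------------------
# derived series


def _accepted_beats(series: RRSeries) -> tuple[np.ndarray, np.ndarray]:
    off = series.beat_offsets[series.accepted]
    ibi = series.intervals[series.accepted]
    return off, ibi


def rr_to_hr_series(series: RRSeries, fs: float = 4.0) -> SignalStream:
    """Instantaneous heart rate (60/RR bpm) interpolated to a uniform grid.

    The grid spans first-to-last accepted beat inclusive; linear
    interpolation between beat times.
    """
    off, ibi = _accepted_beats(series)
    if len(off) < 2:
        raise InsufficientBeats("insufficient beats: need >= 2 accepted")
    hr = 60.0 / ibi
    grid = off[0] + np.arange(int(np.floor((off[-1] - off[0]) * fs)) + 1) / fs
    vals = np.interp(grid, off, hr)
    return SignalStream(
        start_unix=series.start_unix + off[0],
        fs=fs,
        samples=vals.reshape(-1, 1),
        channel_names=("hr",),
        units=("bpm",),
        name="hr_interpolated",
    )


def rr_to_tachogram(series: RRSeries, fs: float = 4.0) -> SignalStream:
    """RR tachogram in ms on a uniform grid (the spectral-analysis input)."""
    off, ibi = _accepted_beats(series)
    if len(off) < 2:
        raise InsufficientBeats("insufficient beats: need >= 2 accepted")
    grid = off[0] + np.arange(int(np.floor((off[-1] - off[0]) * fs)) + 1) / fs
    vals = np.interp(grid, off, ibi * 1000.0)
    return SignalStream(
        start_unix=series.start_unix + off[0],
        fs=fs,
        samples=vals.reshape(-1, 1),
        channel_names=("rr",),
        units=("ms",),
        name="tachogram",
    )


# ---------------------------------------------------------------------------
# HRV measures


def hrv_time_domain(series: RRSeries) -> TimeDomainHRV:
    """Standard time-domain measures over accepted beats.

    mean HR = 60/mean(RR); SDNN = sample standard deviation of RR (ms);
    RMSSD = root mean square of successive differences (ms); pNN50 = % of
    successive differences above 50 ms.
    """
    ibi = series.accepted_intervals()
    if len(ibi) < 2:
        raise InsufficientBeats("insufficient beats: need >= 2 accepted")
    diffs = np.diff(ibi) * 1000.0  # ms
    return TimeDomainHRV(
        mean_hr=float(60.0 / ibi.mean()),
        sdnn=float(np.std(ibi, ddof=1) * 1000.0),
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        pnn50=float(100.0 * np.mean(np.abs(diffs) > 50.0)),
    )


def hrv_frequency_domain(
    hr_series: SignalStream,
    bands: dict[str, tuple[float, float]] | None = None,
    min_duration: float = 120.0,
    welch_segment: float = 120.0,
) -> FreqDomainHRV:
    """Band powers of the mean-removed tachogram by Welch periodogram.

    Pass the ms tachogram from :func:`rr_to_tachogram` to obtain powers in
    ms².  Hann window, 50% overlap, segment length ``welch_segment``
    seconds (clipped to the series length).
    """
    if bands is None:
        bands = DEFAULT_BANDS
    x = hr_series.values
    fs = hr_series.fs
    if len(x) / fs < min_duration:
        raise InsufficientDuration(
            f"insufficient duration: {len(x) / fs:.1f} s < {min_duration} s"
        )
    nperseg = min(len(x), int(round(welch_segment * fs)))
    freqs, psd = sps.welch(
        x - x.mean(),
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )

    def band_power(lo: float, hi: float) -> float:
        mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() < 2:
            return float(psd[mask].sum() * (freqs[1] - freqs[0])) if mask.any() else 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    vlf = band_power(*bands["vlf"])
    lf = band_power(*bands["lf"])
    hf = band_power(*bands["hf"])
    total = float(np.trapezoid(psd, freqs))
    ratio = lf / hf if hf > 0 else float("nan")
    return FreqDomainHRV(
        vlf_power=vlf,
        lf_power=lf,
        hf_power=hf,
        lf_hf_ratio=ratio,
        interpolation_fs=fs,
        total_power=total,
    )
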
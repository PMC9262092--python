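"""Accelerometer magnitude, movement flagging and stream summaries.

The tri-axial accelerometer reports raw signed counts spanning -2g..2g;
dividing the Euclidean magnitude by ``counts_per_g`` (64) yields
acceleration in gravity units, so a device at rest reads ~1 g.  Periods
whose windowed mean magnitude exceeds a threshold (default 1.07 g, i.e.
more than 7% above rest) are flagged: movement is a major artifact source
for both EDA and PPG.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .empatica_io import SignalStream
from .errors import NoAnalyzableData

__all__ = [
    "MovementConfig",
    "StreamSummary",
    "acc_mean_magnitude",
    "flag_high_movement",
    "summarize_stream",
]


@dataclass(frozen=True)
class MovementConfig:
    counts_per_g: float = 64.0
    flag_threshold: float = 1.07  # g
    window: float = 1.0  # rolling-mean window, s

    def __post_init__(self) -> None:
        if self.counts_per_g <= 0 or self.flag_threshold <= 0 or self.window <= 0:
            raise ValueError("movement configuration values must be positive")


@dataclass(frozen=True)
class StreamSummary:
    mean: float
    min: float
    max: float
    median: float
    n: int


def acc_mean_magnitude(
    acc: SignalStream, cfg: MovementConfig = MovementConfig()
) -> SignalStream:
    """Per-sample magnitude sqrt(x^2+y^2+z^2)/counts_per_g in g."""
    if acc.n_channels != 3:
        raise ValueError(f"expected 3 axes, got {acc.n_channels}")
    mag = np.sqrt(np.sum(acc.samples**2, axis=1)) / cfg.counts_per_g
    return replace(
        acc,
        samples=mag.reshape(-1, 1),
        channel_names=("magnitude",),
        units=("g",),
        name="acc_magnitude",
    )


def flag_high_movement(
    mag: SignalStream,
    cfg: MovementConfig = MovementConfig(),
    window: float | None = None,
) -> list[tuple[float, float]]:
    """Maximal stream-relative intervals of sustained high movement.

    The magnitude is smoothed with a centered rolling mean of ``window``
    seconds before thresholding, so single-sample jolts do not flag.
    Returned intervals are disjoint, sorted ``(start_s, end_s)`` pairs.
    """
    if mag.n_channels != 1:
        raise ValueError("flag_high_movement expects the magnitude stream")
    if mag.n_samples == 0:
        return []
    win = window if window is not None else cfg.window
    n_win = max(1, int(round(win * mag.fs)))
    smooth = ndimage.uniform_filter1d(mag.values, size=n_win, mode="nearest")
    above = smooth > cfg.flag_threshold
    edges = np.diff(above.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    return [(s / mag.fs, e / mag.fs) for s, e in zip(starts, ends)]


def summarize_stream(
    stream: SignalStream, mask: np.ndarray | None = None
) -> StreamSummary:
    """Mean/min/max/median over valid samples of a single-channel stream."""
    x = stream.values
    if mask is not None:
        x = x[np.asarray(mask, dtype=bool)]
    if len(x) == 0:
        raise NoAnalyzableData("no analyzable data: no valid samples")
    return StreamSummary(
        mean=float(x.mean()),
        min=float(x.min()),
        max=float(x.max()),
        median=float(np.median(x)),
        n=int(len(x)),
    )
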
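"""Sliding-window segmentation and dynamic connectivity networks.

A dynamic BFCN summarizes time-varying connectivity: the series is cut into
overlapping windows, one connectivity square is built per window, and the
squares are averaged element-wise.  Window coordinates are 0-based and
half-open; window k covers volumes [k*step, k*step + size).  Trailing
volumes that do not fill a complete window are dropped, matching the count
floor((num_volume - window_size) / window_step) + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix, SubjectTimeSeries, static_bfcn
from .errors import InputError, MetricUndefinedError

#: default parameter sweep for the window grid
DEFAULT_WINDOW_SIZES = (50, 70, 90, 110)
DEFAULT_WINDOW_STEPS = (1, 2, 4, 8, 10)


@dataclass(frozen=True)
class SlidingWindowConfig:
    window_size: int
    window_step: int

    def __post_init__(self) -> None:
        if self.window_step < 1:
            raise InputError("window_step must be >= 1")
        if self.window_size < self.window_step:
            raise InputError("window_size must be >= window_step")

    def validate_for(self, num_volume: int) -> None:
        if self.window_size > num_volume:
            raise InputError(
                f"window_size {self.window_size} exceeds num_volume {num_volume}"
            )


def num_windows(num_volume: int, cfg: SlidingWindowConfig) -> int:
    """Number of complete sliding windows fitting in ``num_volume`` volumes."""
    cfg.validate_for(num_volume)
    return (num_volume - cfg.window_size) // cfg.window_step + 1


def extract_windows(ts: SubjectTimeSeries, cfg: SlidingWindowConfig) -> list[SubjectTimeSeries]:
    """Cut a subject's series into its complete sliding-window segments."""
    k = num_windows(ts.num_volume, cfg)
    segments = []
    for w in range(k):
        start = w * cfg.window_step
        segments.append(
            SubjectTimeSeries(
                subject_id=f"{ts.subject_id}/w{w}",
                signals=ts.signals[:, start : start + cfg.window_size],
                roi_labels=ts.roi_labels,
            )
        )
    return segments


def dynamic_bfcn(
    ts: SubjectTimeSeries,
    metric: str,
    cfg: SlidingWindowConfig,
    mic_params=None,
) -> ConnectivityMatrix:
    """Element-wise mean of the per-window connectivity squares."""
    segments = extract_windows(ts, cfg)
    acc = np.zeros((ts.num_roi, ts.num_roi))
    for w, seg in enumerate(segments):
        try:
            acc += static_bfcn(seg, metric, mic_params=mic_params).values
        except MetricUndefinedError as exc:
            raise MetricUndefinedError(
                f"{ts.subject_id}: {metric} undefined in window {w}: {exc}",
                pair=exc.pair,
                window=w,
            ) from exc
    acc /= len(segments)
    return ConnectivityMatrix(
        metric=metric, values=acc, subject_id=ts.subject_id, roi_labels=ts.roi_labels
    )
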
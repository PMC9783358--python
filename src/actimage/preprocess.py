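"""Min-max normalization and fixed-length sliding-window segmentation.

Normalization maps each channel x to (x - xmin) / (xmax - xmin) so every
value lies in [0, 1]; the statistics are either computed from the
recording itself (default) or supplied, e.g. as fixed sensor ranges
(+/-8 g, +/-500 deg/s).  Segmentation cuts the normalized stream into
fixed-length windows (2.5 s = 250 samples at 100 Hz) with a configurable
overlap, 50% by default; each window carries exactly one activity label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .imu_io import ImuRecording

__all__ = [
    "ChannelStats",
    "SegmentReport",
    "Window",
    "normalize",
    "segment",
    "window_starts",
]


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel minimum and maximum used for min-max scaling."""

    xmin: np.ndarray
    xmax: np.ndarray

    def __post_init__(self) -> None:
        xmin = np.atleast_1d(np.asarray(self.xmin, dtype=float))
        xmax = np.atleast_1d(np.asarray(self.xmax, dtype=float))
        if xmin.shape != xmax.shape:
            raise ValueError("xmin and xmax must have the same shape")
        if np.any(xmax < xmin):
            raise ValueError("xmax must be >= xmin for every channel")
        object.__setattr__(self, "xmin", xmin)
        object.__setattr__(self, "xmax", xmax)

    @classmethod
    def from_recording(cls, rec: ImuRecording) -> "ChannelStats":
        return cls(xmin=rec.data.min(axis=1), xmax=rec.data.max(axis=1))

    @classmethod
    def from_ranges(cls, ranges: Sequence[tuple[float, float]]) -> "ChannelStats":
        """Build stats from fixed (lo, hi) sensor ranges, one per channel."""
        lo, hi = zip(*ranges)
        return cls(xmin=np.array(lo, dtype=float), xmax=np.array(hi, dtype=float))


@dataclass
class Window:
    """A fixed-length normalized segment with a single activity label."""

    values: np.ndarray  # (n_channels, window_len), entries in [0, 1]
    label: str
    source_id: str = ""
    start_index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("window values must be a channels x samples matrix")

    @property
    def window_len(self) -> int:
        return self.values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class SegmentReport:
    """Bookkeeping from one segmentation pass."""

    n_windows: int = 0
    n_mixed_discarded: int = 0  # windows spanning more than one label


def normalize(
    rec: ImuRecording, stats: ChannelStats | None = None
) -> tuple[ImuRecording, ChannelStats]:
    """Min-max scale each channel; returns the scaled recording and the
    stats actually used.

    A degenerate channel (xmax == xmin, e.g. a gyro axis during quiet
    standing) maps to all zeros rather than dividing by zero.
    """
    if rec.n_samples == 0:
        raise ValueError("cannot normalize an empty recording")
    if stats is None:
        stats = ChannelStats.from_recording(rec)
    if stats.xmin.shape[0] != rec.n_channels:
        raise ValueError(
            f"stats cover {stats.xmin.shape[0]} channels, recording has {rec.n_channels}"
        )
    span = stats.xmax - stats.xmin
    safe = np.where(span > 0, span, 1.0)
    scaled = (rec.data - stats.xmin[:, None]) / safe[:, None]
    scaled[span == 0, :] = 0.0
    return rec.with_data(scaled), stats


def window_starts(n_samples: int, window_len: int, overlap_fraction: float) -> list[int]:
    """Start offsets of all full windows: multiples of
    ``step = round(window_len * (1 - overlap_fraction))``; a trailing
    partial window is discarded."""
    step = max(1, round(window_len * (1.0 - overlap_fraction)))
    if window_len > n_samples:
        return []
    return list(range(0, n_samples - window_len + 1, step))


def segment(
    rec: ImuRecording,
    window_len: int,
    overlap_fraction: float = 0.5,
    *,
    report: SegmentReport | None = None,
) -> list[Window]:
    """Cut a recording into fixed-length windows with the given overlap.

    Windows whose samples carry more than one label are discarded (the
    count is recorded in ``report`` when given): segmentation is meant
    to run within labeled activity bouts where mixed windows cannot
    occur.  A window longer than the recording yields an empty list and
    a warning.
    """
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    if window_len <= 0:
        raise ValueError(f"window_len must be positive, got {window_len}")
    if window_len > rec.n_samples:
        warnings.warn(
            f"window_len {window_len} exceeds recording length {rec.n_samples}; "
            "no windows produced",
            stacklevel=2,
        )
        return []
    windows: list[Window] = []
    n_mixed = 0
    for start in window_starts(rec.n_samples, window_len, overlap_fraction):
        chunk_labels = rec.labels[start : start + window_len]
        unique = set(chunk_labels.tolist())
        if len(unique) != 1:
            n_mixed += 1
            continue
        windows.append(
            Window(
                values=rec.data[:, start : start + window_len].copy(),
                label=str(unique.pop()),
                source_id=rec.subject_id,
                start_index=start,
            )
        )
    if report is not None:
        report.n_windows += len(windows)
        report.n_mixed_discarded += n_mixed
    return windows
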
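"""Data model and delimited-text I/O for labeled IMU recordings.

An :class:`ImuRecording` is a channels x samples matrix of raw sensor
values (tri-axial accelerometer, optionally plus tri-axial gyroscope)
with one activity label per sample and a declared sampling rate.  The
on-disk format is a plain CSV with one column per channel plus a
``label`` column, optionally preceded by a ``# sample_rate=<Hz>``
comment line.  Units (g or m/s^2, deg/s) are carried as metadata only;
downstream min-max normalization makes the pipeline unit-free.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ACCEL_CHANNELS",
    "IMU_CHANNELS",
    "ClassSet",
    "FormatError",
    "ImuRecording",
    "read_recording",
    "write_recording",
]

#: canonical channel order: accelerometer axes then gyroscope axes
IMU_CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "wx", "wy", "wz")
#: accelerometer-only mode (e.g. 20 Hz smartphone datasets)
ACCEL_CHANNELS: tuple[str, ...] = ("ax", "ay", "az")

_VALID_CHANNEL_COUNTS = (3, 6)
_LABEL_COLUMN = "label"


class FormatError(ValueError):
    """Raised when a recording file does not match the expected layout."""


@dataclass(frozen=True)
class ClassSet:
    """Ordered, unique activity class names.

    The order is fixed and defines the row/column order of every
    confusion matrix built from these classes.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        if len(names) < 2:
            raise ValueError("a class set needs at least 2 classes")
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate class names in {names}")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: object) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown class {name!r}; classes are {self.names}") from None


@dataclass
class ImuRecording:
    """A labeled multichannel inertial time series.

    Parameters
    ----------
    sample_rate:
        Sampling frequency in Hz (> 0).
    channels:
        Ordered channel names; 6 (accel + gyro) or 3 (accel only).
    data:
        ``(len(channels), n_samples)`` array of raw sensor values.
    labels:
        One activity label per sample (length ``n_samples``).
    subject_id:
        Opaque provenance string.
    cohort:
        Cohort tag, e.g. ``HS`` (healthy), ``PD`` (Parkinson's),
        ``SS`` (stroke survivors) or ``other``.
    """

    sample_rate: float
    channels: tuple[str, ...]
    data: np.ndarray
    labels: np.ndarray
    subject_id: str = ""
    cohort: str = "other"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        self.channels = tuple(str(c) for c in self.channels)
        if len(self.channels) not in _VALID_CHANNEL_COUNTS:
            raise ValueError(
                f"expected 3 or 6 channels, got {len(self.channels)}: {self.channels}"
            )
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data must be ({len(self.channels)}, n_samples), got shape {self.data.shape}"
            )
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.shape != (self.data.shape[1],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"{self.data.shape[1]} samples"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sample_rate

    def with_data(self, data: np.ndarray) -> "ImuRecording":
        """Copy of this recording with the sensor matrix replaced."""
        return replace(self, data=data)


def read_recording(
    path: str | Path,
    sample_rate: float | None = None,
    channel_names: Sequence[str] | None = None,
    subject_id: str = "",
    cohort: str = "other",
) -> ImuRecording:
    """Read a CSV recording written by :func:`write_recording`.

    The file must have a header row of channel names plus a ``label``
    column.  A leading ``# sample_rate=<Hz>`` comment line is honored;
    an explicit ``sample_rate`` argument overrides it.

    Raises
    ------
    FormatError
        On a missing/extra column (named in the message), a sensor
        column count other than 3 or 6, or a non-numeric sensor cell
        (reported with its 0-based data row index).
    """
    path = Path(path)
    text = path.read_text()
    file_rate = None
    lines = text.splitlines()
    body_start = 0
    for line in lines:
        if not line.startswith("#"):
            break
        body_start += 1
        stripped = line.lstrip("#").strip()
        if stripped.startswith("sample_rate="):
            file_rate = float(stripped.split("=", 1)[1])
    frame = pd.read_csv(_io.StringIO("\n".join(lines[body_start:])), dtype=str)

    if _LABEL_COLUMN not in frame.columns:
        raise FormatError(f"{path}: missing required column '{_LABEL_COLUMN}'")
    file_channels = tuple(c for c in frame.columns if c != _LABEL_COLUMN)
    if channel_names is not None:
        expected = tuple(channel_names)
        missing = set(expected) - set(file_channels)
        extra = set(file_channels) - set(expected)
        if missing:
            raise FormatError(f"{path}: missing channel column(s) {sorted(missing)}")
        if extra:
            raise FormatError(f"{path}: unexpected column(s) {sorted(extra)}")
        file_channels = expected
    if len(file_channels) not in _VALID_CHANNEL_COUNTS:
        raise FormatError(
            f"{path}: expected 3 or 6 sensor columns, found {len(file_channels)}"
        )

    sensor = frame[list(file_channels)].apply(pd.to_numeric, errors="coerce")
    bad = sensor.isna().to_numpy()
    if bad.any():
        row, col = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-numeric value {frame.iloc[row][file_channels[col]]!r} "
            f"in column '{file_channels[col]}' at row {row}"
        )

    rate = sample_rate if sample_rate is not None else file_rate
    if rate is None:
        raise FormatError(f"{path}: sample rate neither given nor stored in the file")
    return ImuRecording(
        sample_rate=float(rate),
        channels=file_channels,
        data=sensor.to_numpy(dtype=float).T,
        labels=frame[_LABEL_COLUMN].to_numpy(dtype=object),
        subject_id=subject_id,
        cohort=cohort,
    )


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as CSV (header + ``# sample_rate`` comment).

    Sensor values are printed with 9 significant digits, so a
    write/read round trip preserves them well beyond the 6 significant
    digits the format guarantees.
    """
    path = Path(path)
    frame = pd.DataFrame(
        {name: rec.data[i] for i, name in enumerate(rec.channels)}
    )
    frame[_LABEL_COLUMN] = rec.labels
    with open(path, "w", newline="") as fh:
        fh.write(f"# sample_rate={rec.sample_rate:g}\n")
        frame.to_csv(fh, index=False, float_format="%.9g")
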
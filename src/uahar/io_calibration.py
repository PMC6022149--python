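"""Raw 6-axis IMU stream I/O and sensor calibration.

A stream is a fixed-rate sequence of tri-axial accelerometer (g) and
tri-axial gyroscope (deg/s) samples, optionally with a per-sample
activity label.  Calibration converts raw counts to physical units with
per-channel sensitivity coefficients ``k`` and zero-drift offsets ``b``:
``calibrated = raw / k + b``.  Zero drift on consumer MEMS parts is
small, so ``b`` defaults to zero.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: channel order used everywhere: accelerometer x,y,z then gyroscope x,y,z
CHANNELS = ("ax", "ay", "az", "wx", "wy", "wz")


@dataclass
class CalibrationParams:
    """Per-channel sensitivity ``k`` (>0) and zero-drift offset ``b``."""

    k: np.ndarray = field(default_factory=lambda: np.ones(6))
    b: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.k.shape != (6,) or self.b.shape != (6,):
            raise ValueError("CalibrationParams k and b must each have 6 entries")
        self.validate()

    def validate(self) -> None:
        if not np.all(np.isfinite(self.k)) or not np.all(np.isfinite(self.b)):
            raise ValueError("calibration parameters must be finite")
        if np.any(self.k <= 0):
            bad = [CHANNELS[i] for i in np.nonzero(self.k <= 0)[0]]
            raise ValueError(f"sensitivity coefficients must be > 0 (offending: {bad})")


@dataclass
class RawStream:
    """Fixed-rate 6-axis samples, shape (n, 6), plus an optional label track."""

    data: np.ndarray
    rate_hz: float = 50.0
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValueError("stream data must have shape (n_samples, 6)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stream contains non-finite values")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be > 0")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.data):
                raise ValueError("label track length must match sample count")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def accel(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def gyro(self) -> np.ndarray:
        return self.data[:, 3:]

    def slice(self, start: int, stop: int | None = None) -> "RawStream":
        """Sub-stream by sample index (labels sliced alongside)."""
        labels = None if self.labels is None else self.labels[start:stop]
        return RawStream(self.data[start:stop], self.rate_hz, labels)


def _is_numeric_row(row: list[str]) -> bool:
    try:
        for cell in row[:6]:
            float(cell)
    except (ValueError, IndexError):
        return False
    return True


def read_sensor_stream(path: str | Path, rate_hz: float = 50.0) -> RawStream:
    """Read a CSV stream: columns ax,ay,az,wx,wy,wz[,label], one sample per row.

    A non-numeric first row is treated as a header and skipped.  Malformed
    rows raise ``ValueError`` naming the 1-based line number.
    """
    path = Path(path)
    rows: list[list[float]] = []
    labels: list[str] = []
    has_labels = False
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if lineno == 1 and not _is_numeric_row(row):
                continue  # header
            if len(row) < 6:
                raise ValueError(
                    f"{path}, line {lineno}: expected >=6 columns, got {len(row)}"
                )
            try:
                values = [float(c) for c in row[:6]]
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-numeric value ({exc})") from None
            if not all(np.isfinite(values)):
                raise ValueError(f"{path}, line {lineno}: non-finite value")
            rows.append(values)
            if len(row) >= 7 and row[6].strip():
                has_labels = True
                labels.append(row[6].strip())
            else:
                labels.append("")
    if not rows:
        raise ValueError(f"{path}: empty stream file")
    if has_labels and any(lab == "" for lab in labels):
        raise ValueError(f"{path}: label column present but missing on some rows")
    return RawStream(
        np.array(rows, dtype=float),
        rate_hz=rate_hz,
        labels=np.array(labels, dtype=object) if has_labels else None,
    )


def write_sensor_stream(path: str | Path, stream: RawStream, header: bool = True) -> None:
    """Write a stream back to CSV; float repr round-trips bit-identically."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        if header:
            cols = list(CHANNELS) + (["label"] if stream.labels is not None else [])
            writer.writerow(cols)
        for i, row in enumerate(stream.data):
            out = [repr(float(v)) for v in row]
            if stream.labels is not None:
                out.append(str(stream.labels[i]))
            writer.writerow(out)


def calibrate(stream: RawStream, params: CalibrationParams | None = None) -> RawStream:
    """Apply per-channel calibration ``x = raw / k + b``; length preserved."""
    if params is None:
        params = CalibrationParams()
    params.validate()
    data = stream.data / params.k[None, :] + params.b[None, :]
    return RawStream(data, rate_hz=stream.rate_hz, labels=stream.labels)
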
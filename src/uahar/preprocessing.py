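"""Gravity/body-acceleration separation and sliding-window segmentation.

The accelerometer signal mixes the near-DC gravitational component with
body motion.  A zero-phase low-pass Butterworth filter (default order 3,
cutoff 0.3 Hz) estimates gravity; body acceleration is the residual.
Gyroscope channels pass through untouched.  Streams are then cut into
overlapping fixed-length windows (default 1 s at 50 Hz with 50% overlap,
so window k starts at sample 25*(k-1)); a 300-ms fall transient is
always fully contained in at least one such window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_calibration import RawStream


@dataclass
class Window:
    """One analysis window: raw 6-channel block plus body-acceleration block."""

    index: int          # 1-based window number k
    start: int          # 0-based start sample
    samples: np.ndarray  # (L, 6) calibrated samples
    body: np.ndarray     # (L, 3) body acceleration (gravity removed)
    rate_hz: float
    label: str | None = None

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def gyro(self) -> np.ndarray:
        return self.samples[:, 3:]


def separate_gravity(
    stream: RawStream,
    cutoff_hz: float = 0.3,
    order: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Split acceleration into (gravity, body) via zero-phase Butterworth low-pass.

    Returns two (n, 3) arrays with ``gravity + body == stream.accel`` exactly
    (body is computed as the residual).
    """
    nyquist = stream.rate_hz / 2.0
    if cutoff_hz <= 0 or cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)")
    b, a = signal.butter(order, cutoff_hz / nyquist, btype="low")
    padlen = 3 * max(len(a), len(b))
    if len(stream) <= padlen:
        raise ValueError(
            f"stream length {len(stream)} below filter warm-up length {padlen + 1}"
        )
    gravity = signal.filtfilt(b, a, stream.accel, axis=0)
    body = stream.accel - gravity
    return gravity, body


def _majority_label(labels: np.ndarray) -> str:
    """Majority vote; ties resolved toward the label occurring latest in the
    window (falls sit at window end)."""
    uniq, counts = np.unique(labels.astype(str), return_counts=True)
    top = counts.max()
    candidates = set(uniq[counts == top])
    for lab in labels[::-1]:
        if str(lab) in candidates:
            return str(lab)
    return str(uniq[0])  # unreachable


def segment_windows(
    stream: RawStream,
    body: np.ndarray | None = None,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> list[Window]:
    """Cut a stream into overlapping windows of ``round(window_s * rate)`` samples.

    Hop = round(L * (1 - overlap)); only full windows are emitted, so the
    count is floor((N - L) / hop) + 1.  If a label track exists, each window
    gets its majority label.
    """
    n = len(stream)
    length = int(round(window_s * stream.rate_hz))
    if length < 2:
        raise ValueError("window too short for the given rate")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    hop = int(round(length * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap leaves a zero hop")
    if n < length:
        raise ValueError("stream shorter than one window")
    if body is None:
        body = np.zeros_like(stream.accel)
        warnings.warn(
            "segment_windows called without body acceleration; body blocks are zero",
            stacklevel=2,
        )
    if len(body) != n:
        raise ValueError("body acceleration length must match stream length")

    count = (n - length) // hop + 1
    windows: list[Window] = []
    for k in range(count):
        start = hop * k
        block = stream.data[start : start + length]
        label = None
        if stream.labels is not None:
            label = _majority_label(stream.labels[start : start + length])
        windows.append(
            Window(
                index=k + 1,
                start=start,
                samples=block,
                body=body[start : start + length],
                rate_hz=stream.rate_hz,
                label=label,
            )
        )
    return windows


def preprocess_stream(
    stream: RawStream,
    cutoff_hz: float = 0.3,
    order: int = 3,
    window_s: float = 1.0,
    overlap: float = 0.5,
) -> list[Window]:
    """Convenience: gravity separation followed by segmentation."""
    _, body = separate_gravity(stream, cutoff_hz=cutoff_hz, order=order)
    return segment_windows(stream, body=body, window_s=window_s, overlap=overlap)
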
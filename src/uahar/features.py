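"""Time-domain window features and feature normalization.

From each window two magnitude tracks are formed: the Euclidean norm of
the body acceleration (g) and of the angular velocity (deg/s).  Six
statistics per track — mean, population standard deviation, energy
(mean of squares), mean-crossing rate, maximum, minimum — plus the tilt
angle give a 13-dimensional feature vector.

The tilt angle TA is the Euclidean norm of the x- and z-axis angular
velocities integrated (rectangular rule) over the window:
``TA = sqrt((sum wx*dt)^2 + (sum wz*dt)^2)`` in degrees.  It is both the
13th feature and the quantity thresholded by the fall rule, so the raw
(un-normalized) value is carried alongside normalized vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import Window

FEATURE_NAMES = (
    "a_mean", "a_std", "a_energy", "a_mcr", "a_max", "a_min",
    "w_mean", "w_std", "w_energy", "w_mcr", "w_max", "w_min",
    "tilt_angle",
)

#: index of the tilt angle within the feature vector
TA_INDEX = 12


def magnitude(xyz: np.ndarray) -> np.ndarray:
    """Euclidean norm over the last axis: sqrt(x^2 + y^2 + z^2)."""
    xyz = np.asarray(xyz, dtype=float)
    return np.sqrt(np.sum(xyz * xyz, axis=-1))


def tilt_angle(gyro_block: np.ndarray, rate_hz: float) -> float:
    """Norm of the rectangular-rule integrals of wx and wz over the window (deg).

    Integration restarts at each window; there is no carry-over between
    windows.
    """
    gyro_block = np.asarray(gyro_block, dtype=float)
    if gyro_block.ndim != 2 or gyro_block.shape[1] != 3 or len(gyro_block) < 1:
        raise ValueError("gyro block must have shape (L>=1, 3)")
    dt = 1.0 / rate_hz
    ix = np.sum(gyro_block[:, 0]) * dt
    iz = np.sum(gyro_block[:, 2]) * dt
    return float(np.hypot(ix, iz))


def mean_crossing_rate(track: np.ndarray) -> float:
    """Fraction of consecutive sample pairs straddling the track mean.

    A crossing is a strict sign change of ``s - mean(s)``; the count is
    normalized by L-1.
    """
    track = np.asarray(track, dtype=float)
    if len(track) < 2:
        return 0.0
    centered = track - track.mean()
    crossings = np.sum(centered[:-1] * centered[1:] < 0)
    return float(crossings) / (len(track) - 1)


def _track_stats(track: np.ndarray) -> list[float]:
    return [
        float(track.mean()),
        float(track.std()),  # population (1/L) convention
        float(np.mean(track * track)),
        mean_crossing_rate(track),
        float(track.max()),
        float(track.min()),
    ]


def extract_features(window: Window) -> np.ndarray:
    """13-feature vector for one window, ordered as ``FEATURE_NAMES``.

    Acceleration statistics are computed from the body-acceleration
    magnitude (gravity removed); angular-velocity statistics from the raw
    gyroscope magnitude.
    """
    a_mag = magnitude(window.body)
    w_mag = magnitude(window.gyro)
    ta = tilt_angle(window.gyro, window.rate_hz)
    return np.array(_track_stats(a_mag) + _track_stats(w_mag) + [ta], dtype=float)


def feature_matrix(windows: list[Window]) -> tuple[np.ndarray, np.ndarray | None]:
    """Stack per-window features into (M, 13); second element is the window
    label array when label tracks exist, else None."""
    X = np.array([extract_features(w) for w in windows], dtype=float)
    labels = None
    if windows and windows[0].label is not None:
        labels = np.array([w.label for w in windows], dtype=object)
    return X, labels


@dataclass
class Normalizer:
    """Per-feature min-max scaler fitted on training data only.

    Transformed values are ``(x - min) / (max - min)``; a feature that is
    constant on the training set gets scale 1 so it maps to 0.  Test-time
    values outside the training range are not clamped.
    """

    min_: np.ndarray
    scale_: np.ndarray
    method: str = "minmax"

    def __post_init__(self) -> None:
        self.min_ = np.asarray(self.min_, dtype=float)
        self.scale_ = np.asarray(self.scale_, dtype=float)
        if np.any(self.scale_ <= 0):
            raise ValueError("normalizer scales must be > 0")

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.min_) / self.scale_


def fit_normalizer(X: np.ndarray) -> Normalizer:
    """Fit min-max scaling on a training feature matrix (needs >= 2 rows)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("cannot fit a normalizer on an empty training set")
    if len(X) < 2:
        raise ValueError("normalizer fit requires at least 2 training vectors")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = 1.0  # degenerate feature maps to 0
    return Normalizer(min_=lo, scale_=span)


def apply_normalizer(norm: Normalizer, X: np.ndarray) -> np.ndarray:
    """Functional alias for ``norm.transform`` (accepts a vector or matrix)."""
    return norm.transform(X)
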
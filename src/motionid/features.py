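"""Per-window feature engineering for the 56-feature motion signature.

Each 1-second window yields 8 statistics (mean, max, min, RMS, variance,
standard deviation, skewness, excess kurtosis) of 7 signals (yaw, pitch,
roll, the three accelerometer axes, and the accelerometer vector magnitude):
8 x 7 = 56 features, in a stable documented order.

Attitude convention
-------------------
Pitch and roll come from accelerometer tilt under the face-up rest pose
``(0, 0, -1)``:

    pitch = atan2(-ax, sqrt(ay^2 + az^2))
    roll  = atan2(ay, -az)

Yaw is the cumulative trapezoidal integral of the gyroscope yaw-rate (device
Z) channel, reset to zero at each window start — no magnetometer is logged,
so absolute heading is unobservable and only within-window yaw motion is
informative.  Moments are population moments (divide by n); skewness is
``m3 / m2^1.5`` and kurtosis is excess kurtosis ``m4 / m2^2 - 3``, both
defined as 0 for a constant signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .sensor_io import Window

__all__ = [
    "FEATURE_SIGNALS",
    "FEATURE_STATS",
    "FEATURE_NAMES",
    "FeatureVector",
    "RawWindowSequence",
    "attitude_series",
    "vector_magnitude",
    "extract_features",
    "feature_matrix",
    "extract_raw_sequence",
    "raw_sequence_tensor",
]

FEATURE_SIGNALS = (
    "yaw",
    "pitch",
    "roll",
    "accel_x",
    "accel_y",
    "accel_z",
    "vector_magnitude",
)
FEATURE_STATS = (
    "mean",
    "max",
    "min",
    "rms",
    "variance",
    "sd",
    "skewness",
    "kurtosis",
)
FEATURE_NAMES = tuple(
    f"{signal}_{stat}" for signal in FEATURE_SIGNALS for stat in FEATURE_STATS
)

RAW_SEQUENCE_CHANNELS = ("yaw", "pitch", "roll", "accel_x", "accel_y", "accel_z")


@dataclass(frozen=True)
class FeatureVector:
    """One window's 56 features plus window metadata."""

    values: np.ndarray  # (56,)
    user_id: str
    start_time: float
    position: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("features must be finite")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, map(float, self.values)))


@dataclass(frozen=True)
class RawWindowSequence:
    """One window's per-sample 6-channel sequence for the transformer."""

    values: np.ndarray  # (nominal_length, 6): yaw, pitch, roll, ax, ay, az
    user_id: str
    start_time: float
    position: str
    padded: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(RAW_SEQUENCE_CHANNELS):
            raise ValueError(f"expected (n, 6) sequence, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("sequence values must be finite")
        object.__setattr__(self, "values", values)


def _attitude_from_arrays(
    accel: np.ndarray, gyro: np.ndarray, timestamps: np.ndarray
) -> np.ndarray:
    """Vectorized attitude for stacked windows: accel (..., n, 3) -> (..., n, 3)."""
    ax, ay, az = accel[..., 0], accel[..., 1], accel[..., 2]
    pitch = np.arctan2(-ax, np.hypot(ay, az))
    roll = np.arctan2(ay, -az)
    yaw = cumulative_trapezoid(gyro[..., 2], x=timestamps, axis=-1, initial=0.0)
    return np.stack([yaw, pitch, roll], axis=-1)


def attitude_series(window: Window) -> np.ndarray:
    """Per-sample (yaw, pitch, roll) for one window, yaw(first sample) = 0."""
    if len(window) == 0:
        raise ValueError("empty window has no attitude")
    return _attitude_from_arrays(window.accel, window.gyro, window.timestamps)


def vector_magnitude(sample: np.ndarray) -> np.ndarray:
    """Euclidean norm of a triaxial accelerometer sample (or array of them)."""
    arr = np.asarray(sample, dtype=float)
    return np.sqrt(np.sum(arr * arr, axis=-1))


def _signal_stack(
    accel: np.ndarray, gyro: np.ndarray, timestamps: np.ndarray
) -> np.ndarray:
    """(..., n, 7) stack: yaw, pitch, roll, ax, ay, az, vector magnitude."""
    attitude = _attitude_from_arrays(accel, gyro, timestamps)
    vm = vector_magnitude(accel)[..., None]
    return np.concatenate([attitude, accel, vm], axis=-1)


def _stats_block(signals: np.ndarray) -> np.ndarray:
    """The 8 statistics per signal: (..., n, s) -> (..., s * 8) in name order."""
    mean = signals.mean(axis=-2)
    smax = signals.max(axis=-2)
    smin = signals.min(axis=-2)
    rms = np.sqrt(np.mean(signals**2, axis=-2))
    # An exactly constant signal gets exact degenerate statistics (the naive
    # mean of n identical floats need not round back to the value itself).
    constant = smax == smin
    mean = np.where(constant, smax, mean)
    rms = np.where(constant, np.abs(smax), rms)
    centered = signals - mean[..., None, :]
    m2 = np.mean(centered**2, axis=-2)
    m3 = np.mean(centered**3, axis=-2)
    m4 = np.mean(centered**4, axis=-2)
    sd = np.sqrt(m2)
    ok = (m2 > 0) & ~constant
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(ok, m3 / np.where(ok, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(ok, m4 / np.where(ok, m2, 1.0) ** 2 - 3.0, 0.0)
    m2 = np.where(constant, 0.0, m2)
    sd = np.where(constant, 0.0, sd)
    # (..., s, 8) then flatten the trailing two axes -> signal-major order.
    block = np.stack([mean, smax, smin, rms, m2, sd, skew, kurt], axis=-1)
    return block.reshape(block.shape[:-2] + (block.shape[-2] * block.shape[-1],))


def extract_features(window: Window) -> FeatureVector:
    """Compute the 56-feature vector for one window (needs >= 2 samples)."""
    if len(window) < 2:
        raise ValueError("feature extraction requires a window with >= 2 samples")
    values = _stats_block(_signal_stack(window.accel, window.gyro, window.timestamps))
    return FeatureVector(
        values=values,
        user_id=window.user_id,
        start_time=window.start_time,
        position=window.position,
    )


def feature_matrix(windows: list[Window]) -> np.ndarray:
    """Vectorized 56-feature matrix for equal-length windows, (n_win, 56).

    Falls back to per-window extraction when window lengths differ.  Agrees
    with :func:`extract_features` row for row.
    """
    if not windows:
        return np.empty((0, len(FEATURE_NAMES)))
    lengths = {len(w) for w in windows}
    if len(lengths) == 1 and lengths.pop() >= 2:
        accel = np.stack([w.accel for w in windows])
        gyro = np.stack([w.gyro for w in windows])
        ts = np.stack([w.timestamps for w in windows])
        return _stats_block(_signal_stack(accel, gyro, ts))
    return np.stack([extract_features(w).values for w in windows])


def extract_raw_sequence(
    window: Window, nominal_length: int | None = None
) -> RawWindowSequence:
    """Per-sample (yaw, pitch, roll, ax, ay, az) sequence for one window.

    Windows shorter than ``nominal_length`` are right-padded by repeating the
    last sample and flagged; longer windows are an error (the segmenter never
    produces them for a uniform stream).
    """
    if len(window) == 0:
        raise ValueError("cannot build a raw sequence from an empty window")
    attitude = attitude_series(window)
    seq = np.concatenate([attitude, window.accel], axis=-1)
    padded = False
    if nominal_length is not None:
        if len(seq) > nominal_length:
            raise ValueError(
                f"window has {len(seq)} samples, more than nominal {nominal_length}"
            )
        if len(seq) < nominal_length:
            pad = np.tile(seq[-1], (nominal_length - len(seq), 1))
            seq = np.concatenate([seq, pad], axis=0)
            padded = True
    return RawWindowSequence(
        values=seq,
        user_id=window.user_id,
        start_time=window.start_time,
        position=window.position,
        padded=padded,
    )


def raw_sequence_tensor(windows: list[Window], nominal_length: int) -> np.ndarray:
    """Stacked raw sequences, (n_win, nominal_length, 6)."""
    return np.stack(
        [extract_raw_sequence(w, nominal_length).values for w in windows]
    )
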
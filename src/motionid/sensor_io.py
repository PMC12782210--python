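"""Reading, windowing and normalizing SensorLog-style sensor streams.

The on-disk dialect mirrors the iOS SensorLog app: a CSV with a monotone
since-reboot timestamp column (``accelerometerTimestamp_sinceReboot``), three
accelerometer columns in gravity units and three gyroscope columns in rad/s.
Logging-layer buffering can duplicate rows, so ingestion deduplicates on the
since-reboot timestamp (first occurrence kept) before validating monotonicity.

Streams are cut into non-overlapping 1-second windows anchored at the
recording's first timestamp; a trailing partial second is dropped.  Feature
matrices are min-max normalized with parameters fit on the training split
only (scikit-learn's ``MinMaxScaler``; test values outside the training range
are deliberately not clipped).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import NotFittedError
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "LAYING",
    "SITTING",
    "TIMESTAMP_COLUMN",
    "SensorFormatError",
    "SensorDataError",
    "SensorRecording",
    "Window",
    "read_sensorlog_csv",
    "recording_to_frame",
    "segment_windows",
    "NormalizationParams",
    "MinMaxNormalizer",
    "fit_minmax",
    "apply_minmax",
]

LAYING = "laying"
SITTING = "sitting"

TIMESTAMP_COLUMN = "accelerometerTimestamp_sinceReboot"
ACCEL_COLUMNS = ("accelX", "accelY", "accelZ")
GYRO_COLUMNS = ("gyroX", "gyroY", "gyroZ")
REQUIRED_COLUMNS = (TIMESTAMP_COLUMN,) + ACCEL_COLUMNS + GYRO_COLUMNS


class SensorFormatError(ValueError):
    """The file does not conform to the SensorLog CSV dialect."""


class SensorDataError(ValueError):
    """The file parses but its contents violate stream invariants."""


@dataclass
class SensorRecording:
    """One user's raw timestamped 6-axis stream with per-sample position."""

    user_id: str
    timestamps: np.ndarray  # (n,) seconds since reboot, strictly increasing
    accel: np.ndarray  # (n, 3) gravity units
    gyro: np.ndarray  # (n, 3) rad/s
    position: np.ndarray  # (n,) labels in {laying, sitting}

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.position = np.asarray(self.position)
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise SensorDataError("accel/gyro must be (n, 3) matching timestamps")
        if self.position.shape != (n,):
            raise SensorDataError("position must have one label per sample")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise SensorDataError("timestamps must be strictly increasing")
        for name, arr in (("timestamps", self.timestamps), ("accel", self.accel), ("gyro", self.gyro)):
            if not np.all(np.isfinite(arr)):
                raise SensorDataError(f"{name} contains non-finite values")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class Window:
    """A non-overlapping 1-second sub-stream of a recording."""

    user_id: str
    start_time: float
    position: str  # majority label over the window
    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __len__(self) -> int:
        return len(self.timestamps)


def recording_to_frame(rec: SensorRecording) -> pd.DataFrame:
    """The canonical column layout used by :func:`~motionid.synthetic.write_sensorlog_csv`."""
    data = {TIMESTAMP_COLUMN: rec.timestamps}
    for j, col in enumerate(ACCEL_COLUMNS):
        data[col] = rec.accel[:, j]
    for j, col in enumerate(GYRO_COLUMNS):
        data[col] = rec.gyro[:, j]
    data["position"] = rec.position
    data["user_id"] = rec.user_id
    return pd.DataFrame(data)


def read_sensorlog_csv(path, user_id: str | None = None) -> SensorRecording:
    """Read a SensorLog-style CSV into a validated :class:`SensorRecording`.

    Rows sharing a since-reboot timestamp are collapsed to their first
    occurrence (duplicates arise from logging-layer buffering of an unchanged
    sensor read).  A missing required column raises
    :class:`SensorFormatError` naming the column; timestamps that remain
    non-monotone after deduplication raise :class:`SensorDataError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SensorFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )
    if "position" not in df.columns:
        raise SensorFormatError(
            f"{path.name}: missing required column(s): position"
        )
    df = df.drop_duplicates(subset=TIMESTAMP_COLUMN, keep="first")
    ts = df[TIMESTAMP_COLUMN].to_numpy(dtype=float)
    if len(ts) > 1 and not np.all(np.diff(ts) > 0):
        raise SensorDataError(
            f"{path.name}: timestamps not strictly increasing after deduplication"
        )
    numeric = df[list(ACCEL_COLUMNS + GYRO_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(numeric)) or not np.all(np.isfinite(ts)):
        raise SensorDataError(f"{path.name}: missing or non-finite sensor values")
    if user_id is None:
        if "user_id" in df.columns:
            user_id = str(df["user_id"].iloc[0])
        else:
            user_id = path.stem
    return SensorRecording(
        user_id=user_id,
        timestamps=ts,
        accel=numeric[:, :3],
        gyro=numeric[:, 3:],
        position=df["position"].to_numpy(),
    )


def _majority_label(labels: np.ndarray) -> str:
    values, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    tied = set(values[counts == best])
    if len(tied) == 1:
        return str(tied.pop())
    # Exact tie: the label occurring earliest in the window wins.
    for lab in labels:
        if lab in tied:
            return str(lab)
    raise AssertionError("unreachable")


def segment_windows(rec: SensorRecording) -> list[Window]:
    """Cut a recording into non-overlapping 1-second windows.

    Windows tile the stream from its first timestamp in whole seconds; the
    window count is the floor of the recording duration in seconds (a trailing
    partial second is dropped).  Duration counts each sample as covering one
    nominal sampling interval, so an exactly 15-minute 100 Hz stream yields
    900 windows.  Recordings shorter than one second yield an empty list.
    """
    n = len(rec)
    if n < 2:
        return []
    t = rec.timestamps
    dt_nominal = float(np.median(np.diff(t)))
    duration = (t[-1] - t[0]) + dt_nominal
    # Half-sample tolerance absorbs float jitter from the since-reboot offset
    # (t0 + k/fs minus t0 need not equal k/fs exactly).
    n_windows = int(np.floor(duration + 0.5 * dt_nominal))
    if n_windows < 1:
        return []
    rel = t - t[0]
    # searchsorted on the integer-second boundaries; samples at an exact
    # boundary open the next window, and a sample within half a sampling
    # interval below a boundary is snapped up to it.
    edges = np.searchsorted(
        rel, np.arange(n_windows + 1) - 0.5 * dt_nominal, side="left"
    )
    windows = []
    for w in range(n_windows):
        lo, hi = edges[w], edges[w + 1]
        sl = slice(lo, hi)
        windows.append(
            Window(
                user_id=rec.user_id,
                start_time=float(t[0] + w),
                position=_majority_label(rec.position[sl]),
                timestamps=t[sl],
                accel=rec.accel[sl],
                gyro=rec.gyro[sl],
            )
        )
    return windows


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature training min/max, serializable for audit."""

    feature_min: np.ndarray
    feature_max: np.ndarray

    def to_dict(self) -> dict:
        return {
            "feature_min": [float(v) for v in self.feature_min],
            "feature_max": [float(v) for v in self.feature_max],
        }


class MinMaxNormalizer:
    """Leakage-free min-max normalization: fit on training rows only.

    ``transform`` maps ``x -> (x - min) / (max - min)`` with constant training
    features mapping to 0; test values outside the training range are not
    clipped.  Backed by scikit-learn's ``MinMaxScaler`` (``clip=False``).
    """

    def __init__(self) -> None:
        self._scaler = MinMaxScaler(clip=False)
        self._fitted = False

    def fit(self, train_matrix: np.ndarray) -> "MinMaxNormalizer":
        X = np.asarray(train_matrix, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("fit requires a 2-D matrix with at least 2 rows")
        self._scaler.fit(X)
        self._fitted = True
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise NotFittedError("MinMaxNormalizer.transform called before fit")
        return self._scaler.transform(np.asarray(matrix, dtype=float))

    @property
    def params(self) -> NormalizationParams:
        if not self._fitted:
            raise NotFittedError("normalization parameters requested before fit")
        return NormalizationParams(
            feature_min=self._scaler.data_min_.copy(),
            feature_max=self._scaler.data_max_.copy(),
        )


def fit_minmax(train_matrix: np.ndarray) -> MinMaxNormalizer:
    """Fit min-max parameters on the training matrix only."""
    return MinMaxNormalizer().fit(train_matrix)


def apply_minmax(params: MinMaxNormalizer, matrix: np.ndarray) -> np.ndarray:
    """Apply fitted parameters; never mutates the stored parameters."""
    return params.transform(matrix)
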
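import numpy as np
import pytest

from motionid import ProtocolSpec, sample_cohort, simulate_recording
from motionid.experiments import CohortData
from motionid.sensor_io import LAYING, SITTING, Window


@pytest.fixture(scope="session")
def default_protocol():
    return ProtocolSpec()


@pytest.fixture(scope="session")
def fast_protocol():
    """Full protocol shape (10 + 5 min) at a reduced sampling rate."""
    return ProtocolSpec(sample_rate_hz=20)


@pytest.fixture(scope="session")
def small_cohort_data(fast_protocol):
    """An 8-user cohort windowed and feature-extracted, with raw sequences."""
    cohort = sample_cohort(8, seed=11, separation=3.0)
    recs = [
        simulate_recording(sig, fast_protocol, seed=500 + i)
        for i, sig in enumerate(cohort)
    ]
    return CohortData.from_recordings(recs, fast_protocol, include_sequences=True)


def make_window(accel, gyro=None, timestamps=None, user_id="u0", position=LAYING):
    accel = np.asarray(accel, dtype=float)
    n = len(accel)
    if gyro is None:
        gyro = np.zeros((n, 3))
    if timestamps is None:
        timestamps = np.arange(n) / 100.0
    return Window(
        user_id=user_id,
        start_time=float(timestamps[0]) if n else 0.0,
        position=position,
        timestamps=np.asarray(timestamps, dtype=float),
        accel=accel,
        gyro=np.asarray(gyro, dtype=float),
    )


@pytest.fixture
def random_window_factory():
    def factory(rng, n=100):
        return make_window(
            accel=rng.normal(0, 1, (n, 3)),
            gyro=rng.normal(0, 1, (n, 3)),
            timestamps=np.arange(n) / 100.0,
        )

    return factory
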
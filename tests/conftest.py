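import numpy as np
import pytest

from neuroscreen import CohortSimSpec, ImuSeries, ScalarSignal, simulate_feature_cohort


@pytest.fixture(scope="session")
def pilot_cohort():
    """23-subject cohort (15 no_DN / 8 DN) mirroring the pilot study."""
    return simulate_feature_cohort(CohortSimSpec(seed=20240329))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(ax, ay, az, sample_rate=100.0, gap_mask=None):
    """Six-axis series with zero gyro channels from three accel arrays."""
    ax = np.asarray(ax, dtype=float)
    n = ax.size
    zeros = np.zeros(n)
    return ImuSeries(
        sample_rate,
        np.arange(n) / sample_rate,
        ax=ax,
        ay=np.asarray(ay, dtype=float),
        az=np.asarray(az, dtype=float),
        gx=zeros,
        gy=zeros.copy(),
        gz=zeros.copy(),
        gap_mask=gap_mask,
    )


def sine_signal(freq, sample_rate=100.0, duration=30.0, amplitude=1.0, offset=0.0):
    t = np.arange(int(duration * sample_rate)) / sample_rate
    return ScalarSignal(sample_rate, offset + amplitude * np.sin(2 * np.pi * freq * t))
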
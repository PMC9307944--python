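import numpy as np
import pytest

from hrvsuite.signal_core import PeakSeries, RRISeries, peaks_to_rri
from hrvsuite.synthetic import SyntheticSpec, generate_rri


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def stationary_recording():
    """25-minute stationary recording with mild autocorrelated noise."""
    spec = SyntheticSpec(
        mean_rri=800.0, sd_rri=40.0, duration=25 * 60, ar1_coeff=0.3, seed=7
    )
    peaks, rri, truth = generate_rri(spec)
    return peaks, rri, truth


@pytest.fixture
def short_segment():
    """One 5-minute segment worth of modulated RRI."""
    spec = SyntheticSpec(
        mean_rri=800.0,
        sd_rri=25.0,
        duration=300.0,
        modulation=((0.1, 20.0), (0.25, 15.0)),
        seed=3,
    )
    peaks, rri, _ = generate_rri(spec)
    return peaks, rri


def make_peaks(times, fs=1000.0):
    return PeakSeries(np.asarray(times), sampling_rate=fs)


def make_rri(intervals):
    return RRISeries(np.asarray(intervals, dtype=float))


@pytest.fixture
def make_peaks_fixture():
    return make_peaks


@pytest.fixture
def make_rri_fixture():
    return make_rri
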
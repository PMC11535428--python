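import numpy as np
import pytest
from hypothesis import settings

from pttkit import BolusParams, PeakConfig, TimeSignalCurve

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240521)


@pytest.fixture
def noise_free_params():
    """Noise-free bolus on a regular 1.0 s grid with recirculation present."""
    return BolusParams(noise_sd=0.0, rr_mean=1.0, rr_sd=0.0, n_beats=60, seed=0)


@pytest.fixture
def discrete_config():
    return PeakConfig(refinement="discrete")


def make_curve(values, times=None, chamber="RV"):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    return TimeSignalCurve(np.asarray(times, dtype=float), values, chamber)


@pytest.fixture
def triangle_curve():
    return make_curve([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0])
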
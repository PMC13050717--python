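import numpy as np
import pytest

from xenphys.imaging import MovieStack, Trace, compute_baseline, compute_dff
from xenphys.simulate import COHORT_PRESETS, default_geometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_geometry():
    return default_geometry((48, 48))


@pytest.fixture
def random_movie(rng):
    data = rng.uniform(50.0, 150.0, size=(20, 12, 10))
    return MovieStack(data, fs=2.0)


@pytest.fixture
def random_dff(random_movie):
    return compute_dff(random_movie, compute_baseline(random_movie))


def make_trace(values, fs=2.0):
    return Trace(np.asarray(values, dtype=float), fs)


@pytest.fixture(scope="session")
def control_preset():
    return COHORT_PRESETS["control"]


@pytest.fixture(scope="session")
def crispant_preset():
    return COHORT_PRESETS["crispant"]
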
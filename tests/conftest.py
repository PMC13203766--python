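import numpy as np
import pytest

from dyadflow import (
    EntropyParams,
    PreparedDyad,
    ScaleGrid,
    SimConfig,
    generate_dyad,
)


@pytest.fixture(scope="session")
def short_recording():
    """One 5-minute coupled dyad with default physiology."""
    return generate_dyad(SimConfig(duration=300.0), seed=11, dyad_id="FIX-000")


@pytest.fixture(scope="session")
def prepared(short_recording):
    return PreparedDyad.from_recording(short_recording, fs=20.0)


@pytest.fixture(scope="session")
def fast_params():
    """Estimator settings sized for test fixtures, not full recordings."""
    return EntropyParams(n_surrogates=4, max_vectors=1500, min_vectors=50)


@pytest.fixture(scope="session")
def small_grid():
    return ScaleGrid(taus=(0.25, 0.5, 1.0, 2.5, 5.0), summary_interval=(0.5, 2.5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
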
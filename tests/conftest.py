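import numpy as np
import pytest

from rattlekit.containers import MagnitudeSeries, Provenance
from rattlekit.synth import default_session_config, generate_session


@pytest.fixture(scope="session")
def coupled_session():
    """One default-layout session, phase-locked arms, zero lag."""
    cfg = default_session_config(rng_seed=11, coupling=1.0)
    left, right, track, truth = generate_session(cfg)
    return cfg, left, right, track, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_magnitude(values, fs=60.0, provenance=Provenance.SMOOTHED):
    values = np.asarray(values, dtype=float)
    return MagnitudeSeries(np.arange(len(values)) / fs, values, fs, provenance)


@pytest.fixture()
def magnitude_factory():
    return make_magnitude
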
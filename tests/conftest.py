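import numpy as np
import pytest

from whisksel import SynthConfig, generate_session
from whisksel.io import write_session


@pytest.fixture(scope="session")
def small_session():
    """A modest synthetic session shared by read-only tests."""
    return generate_session(SynthConfig(n_trials=250, n_units=8, seed=11))


@pytest.fixture(scope="session")
def session_dirs(tmp_path_factory):
    """Two synthetic sessions written as standard file bundles."""
    root = tmp_path_factory.mktemp("sessions")
    manifests = []
    for k in range(2):
        session = generate_session(SynthConfig(n_trials=250, n_units=8, seed=21 + k))
        manifests.append(write_session(session, root / f"s{k}", f"s{k}"))
    return manifests


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
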
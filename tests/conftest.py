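import numpy as np
import pytest
from hypothesis import settings

import olfnet

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def default_config():
    return olfnet.default_config()


@pytest.fixture(scope="session")
def naive_net():
    """A freshly built circuit with default parameters (session-scoped;
    tests that mutate state must reset or build their own)."""
    return olfnet.build_network(seed=0)


@pytest.fixture(scope="session")
def trained_state():
    """A circuit trained on one odor for nine 1 s sessions, with the naive
    session statistics kept for reference.  Built once per test session."""
    net = olfnet.build_network(seed=11)
    odor_rng = np.random.default_rng(101)
    odor = olfnet.generate_odor(odor_rng, id="trained")
    net.reset_state()
    first = net.run(odor, 1000.0, reset=True)
    per_session = [first]
    for _ in range(8):
        per_session.append(net.run(odor, 1000.0, reset=True))
    return {
        "net": net,
        "odor": odor,
        "odor_rng": odor_rng,
        "sessions": per_session,
        "weights": net.W.copy(),
    }
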
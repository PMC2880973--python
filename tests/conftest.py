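import numpy as np
import pytest

from phasewave import simulate as sim


@pytest.fixture(scope="session")
def study():
    """One full-scale simulated study bundle shared across tests."""
    return sim.simulate_study(seed=11)


@pytest.fixture(scope="session")
def phases7():
    return sim.make_phase_annotation(sim.default_phase_labels(7))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
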
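import numpy as np
import pytest

from copve import make_scenario, simulate_trial


@pytest.fixture(scope="session")
def trial_ii():
    """One full-size trial from the logistic-truth scenario with an
    age effect (seed fixed for reproducibility)."""
    return simulate_trial(make_scenario("ii"), seed=42)


@pytest.fixture(scope="session")
def trial_iv():
    """One full-size trial from the Hill-truth scenario with an age
    effect."""
    return simulate_trial(make_scenario("iv"), seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
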
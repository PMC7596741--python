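import numpy as np
import pytest

from m1decode import preprocess, synth


@pytest.fixture(scope="session")
def small_session():
    """20-unit, 20-trial center-out session with known tuning."""
    return synth.make_synthetic_session({"n_units": 20, "n_trials": 20}, seed=1)


@pytest.fixture(scope="session")
def small_binned(small_session):
    session, _ = small_session
    return preprocess.make_binned(session)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
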
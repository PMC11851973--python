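import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_session():
    """A rendered two-block session shared by the round-trip tests."""
    from emosearch.synth import SessionConfig, simulate_session

    cfg = SessionConfig(seed=3, n_blocks=2)
    return simulate_session(cfg, participant=0, render_gaze=True)
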
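import warnings

import numpy as np
import pytest
from hypothesis import settings

import vipmode as v

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from vipmode.preprocessing import TraceSet, align_trials, compute_dff


@pytest.fixture(scope="session")
def small_session():
    """A compact but complete synthetic session shared across tests."""
    cfg = v.SessionConfig(n_neurons=30, n_trials=48, seed=11)
    return v.generate_session(cfg)


@pytest.fixture(scope="session")
def small_aligned(small_session):
    s = small_session
    dff = compute_dff(TraceSet(s.traces, s.sample_rate))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return align_trials(dff, s.trials, "expected_reinforcement", (-2.0, 5.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
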
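import numpy as np
import pytest
from hypothesis import settings

from synscale.synthetic import MiniTraceParams, generate_mepsc_trace

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture
def noiseless_params():
    """Fast, noise-free mEPSC generator settings for exact fixtures."""
    return MiniTraceParams(duration=2.0, sampling_rate=10_000.0,
                           event_rate=0.0, noise_sd=0.0)


@pytest.fixture
def single_event_trace(noiseless_params):
    """A 2 s noiseless trace holding one 20 pA event at t=0.5 s."""
    return generate_mepsc_trace(noiseless_params, events=[(0.5, 20.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
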
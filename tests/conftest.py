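import warnings

import numpy as np
import pytest

from rhythmdecode import SynthConfig, synthesize

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_session():
    """30-trial session with LFP and thermocouple, shared across tests."""
    return synthesize(SynthConfig(n_trials=30, seed=11))


@pytest.fixture(scope="session")
def spikes_session():
    """60-trial spikes-only session (no LFP) for behavioral/spatial tests."""
    return synthesize(SynthConfig(n_trials=60, seed=13), with_lfp=False,
                      with_thermo=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
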
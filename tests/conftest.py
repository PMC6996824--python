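import numpy as np
import pytest

from sparktono import eye_config, phantom_config, synthesize_trace


@pytest.fixture(scope="session")
def eye_trace_clean():
    """Noiseless eye-mode trace at 20 mmHg (2 MS/s, 6 ms)."""
    return synthesize_trace(eye_config(20.0))


@pytest.fixture(scope="session")
def phantom_trace_clean():
    """Noiseless phantom-mode trace at 30 mmHg."""
    return synthesize_trace(phantom_config(30.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
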
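import numpy as np
import pytest

from eegfuse.synthetic import SynthParams, simulate_state_sequence, synthesize_recording
from eegfuse.types import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(seed=0, duration=10.0, snr=4.0, drift=0.2, **kwargs):
    """One default-condition synthetic subject."""
    params = SynthParams(
        duration=duration, snr=snr, drift_amplitude=drift, seed=seed, **kwargs
    )
    truth = simulate_state_sequence(params)
    rec = synthesize_recording(params, truth, f"subj{seed}", "HC")
    return params, truth, rec


@pytest.fixture
def small_subject():
    return make_recording(seed=1, duration=10.0)


@pytest.fixture
def random_recording(rng):
    data = rng.standard_normal((5, 400)) * 20
    return Recording("rnd", "HC", [f"ch{i}" for i in range(5)], 200.0, data)
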
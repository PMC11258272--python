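import numpy as np
import pytest

from sleepmap import synthetic as syn


@pytest.fixture(scope="session")
def default_recording_day():
    """One simulated day: three-state hypnogram plus matching EEG/EMG."""
    hyp3, hyp_manifest = syn.simulate_three_state(n_epochs=2700, seed=11)
    rec, rec_manifest = syn.simulate_recording(hyp3, seed=12)
    return hyp3, rec, rec_manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
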
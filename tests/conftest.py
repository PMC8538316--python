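import numpy as np
import pytest

from chewcount.synthetic import ChewScenario, generate_chew_signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_scenario():
    """Noise-free, event-free clip: 1 Hz chewing for 60 s -> exactly 60 chews."""
    return ChewScenario(
        chew_rate_hz=1.0, rate_jitter_frac=0.0, amplitude_jitter_frac=0.0,
        n_bites=0, n_swallow_pauses=0, noise_sd_frac=0.0, drift_amplitude_px=0.0,
        seed=7,
    )


@pytest.fixture
def clean_signal(clean_scenario):
    return generate_chew_signal(clean_scenario)
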
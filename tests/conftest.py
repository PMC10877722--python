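import numpy as np
import pytest

from cavitrack import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast-to-render configuration for image-level tests."""
    return SyntheticConfig(
        temperatures=(20.0, 40.0, 60.0),
        trials_per_temperature=1,
        frames_per_trial=20,
        image_size=(96, 128),
        n_artifacts=1,
        max_rendered_bubbles=30,  # what the smaller frame can hold concurrently
    )


@pytest.fixture
def clean_config():
    """Noise-free, artifact-free config where detection should be exact."""
    return SyntheticConfig(
        temperatures=(20.0, 40.0, 60.0),
        trials_per_temperature=1,
        frames_per_trial=20,
        image_size=(96, 128),
        noise_sd=0.0,
        n_artifacts=0,
    )
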
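import numpy as np
import pytest

from glottikit import preprocessing, synthetic


@pytest.fixture(scope="session")
def small_video():
    """A short noiseless clip with a vertical midline (geometry tests)."""
    params = synthetic.SynthParams(
        height=48, width=32, n_frames=12, cycle_frames=12,
        midline_center=(16.0, 24.0), glottis_length=20.0,
        max_half_width=4.0, noise_sd=0.0, seed=3)
    return synthetic.generate_video(params)


@pytest.fixture(scope="session")
def noisy_video():
    params = synthetic.SynthParams(
        height=48, width=32, n_frames=10, cycle_frames=10,
        midline_angle=8.0, midline_center=(16.0, 24.0),
        glottis_length=22.0, max_half_width=5.0, noise_sd=0.04, seed=17)
    return synthetic.generate_video(params)


@pytest.fixture(scope="session")
def prepared_samples(noisy_video):
    return preprocessing.prepare_video(noisy_video, (48, 32), radius=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
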
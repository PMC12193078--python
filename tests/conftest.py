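import numpy as np
import pytest

from cxrtriad.prep import PrepConfig, preprocess
from cxrtriad.synthpack import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """200 separable 3-class images at the desk-scale study conditions."""
    return generate_dataset(
        SynthConfig(n_images=200, image_side=32, seed=1, opacity_contrast=0.5, noise_sd=0.05)
    )


@pytest.fixture(scope="session")
def small_pixel_matrix(small_dataset):
    """Preprocessed (N, 256) matrix of the session dataset (16x16, z-scored)."""
    cfg = PrepConfig(smoothing_Z=0.8, target_size=16)
    return np.stack(
        [preprocess(im, cfg).values.ravel() for im in small_dataset.images]
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
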
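import numpy as np
import pytest

from wheatear import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def dense_scene():
    """A mid-size cluttered scene shared by augmentation/metric tests."""
    return generate_scene(SceneSpec(image_size=(128, 128), n_ears=40,
                                    overlap_fraction=0.5, seed=11))


@pytest.fixture(scope="session")
def sparse_scene():
    return generate_scene(SceneSpec(image_size=(96, 96), n_ears=6,
                                    overlap_fraction=0.0, background="plain", seed=3))
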
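import numpy as np
import pytest

from sgtn.hsi_data import GroundTruthMap, HSICube
from sgtn.synthetic_scene import SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """24x24, 8 bands, 3 classes, mild noise: cheap end-to-end material."""
    spec = SceneSpec(rows=24, columns=24, bands=8, n_classes=3,
                     noise_sd=0.02, unlabeled_fraction=0.1, seed=3)
    return generate_scene(spec)


@pytest.fixture
def tiny_cube(rng):
    return HSICube(rng.uniform(size=(10, 12, 5)), name="tiny")


@pytest.fixture
def tiny_gt(rng):
    labels = rng.integers(0, 4, size=(10, 12))
    labels[0, 0] = 1  # make sure every class occurs
    labels[0, 1] = 2
    labels[0, 2] = 3
    return GroundTruthMap(labels)
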
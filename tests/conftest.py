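import numpy as np
import pytest

from multispace import (
    BackboneConfig,
    ColorImage,
    GrayImage,
    build_backbone,
    generate_feature_fixture,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def seeded_backbone():
    return build_backbone(BackboneConfig(seed=7))


@pytest.fixture(scope="session")
def feature_fixture():
    """Separable paired features: separation 5, 100 samples per class."""
    return generate_feature_fixture(n_per_class=100, separation=5.0, seed=11)


@pytest.fixture()
def random_gray(rng):
    def make(h=9, w=9):
        return GrayImage(rng.integers(0, 256, size=(h, w)))

    return make


@pytest.fixture()
def random_rgb(rng):
    def make(h=64, w=64):
        return ColorImage(rng.integers(0, 256, size=(h, w, 3)))

    return make
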
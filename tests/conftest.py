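import numpy as np
import pytest

from lungscreen.fixtures import FixtureSpec, make_feature_table, make_image_dataset


@pytest.fixture(scope="session")
def small_images():
    """30 synthetic 32x32 images, 3 classes."""
    return make_image_dataset(FixtureSpec(n_per_class=10,
                                          image_size=(32, 32, 3), seed=7))


@pytest.fixture(scope="session")
def planted_table():
    """300 x 100 planted-feature table: 10 informative columns, effect 4."""
    return make_feature_table(100, 100, 10, 4.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
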
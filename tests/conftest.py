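import numpy as np
import pytest

from vtloc.io import AnnotatedImage
from vtloc.phantom import PhantomConfig, generate_corpus
from vtloc.schema import load_schema


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def small_corpus():
    """2 subjects x 3 classes of 64x64 phantom originals."""
    return generate_corpus(PhantomConfig(n_subjects=2, n_classes=3,
                                         image_size=(64, 64), rng_seed=11))


@pytest.fixture()
def single_item(schema):
    """One synthetic annotated image with landmarks on a ramp image."""
    rng = np.random.default_rng(5)
    image = rng.integers(0, 256, size=(64, 64)).astype(float)
    landmarks = np.column_stack([rng.uniform(5, 58, 21), rng.uniform(5, 58, 21)])
    return AnnotatedImage(image=image, landmarks=landmarks,
                          subject_id="S0", class_id="C0")
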
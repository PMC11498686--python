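import numpy as np
import pytest

from medifuse.features import make_fixture_extractor
from medifuse.siamese import build_snn, make_patch_pairs, train_snn
from medifuse.synthetic import make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_extractor():
    return make_fixture_extractor(seed=0)


@pytest.fixture(scope="session")
def synthetic_pair():
    """One default synthetic multimodal pair (64x64 keeps tests quick)."""
    return make_pair(seed=1, size=(64, 64))


@pytest.fixture(scope="session")
def trained_snn():
    """A quickly trained Siamese model shared by the non-acceptance tests.

    Small corpus and few epochs: enough to separate sharp from blurred
    patches, cheap enough to train once per session.
    """
    data = make_patch_pairs(seed=11, n=300)
    model = build_snn(seed=11)
    model, acc = train_snn(model, data, epochs=6, seed=11)
    return model, acc
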
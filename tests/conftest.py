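import numpy as np
import pytest

from crowdgp.data import MultiAnnotatorDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset():
    """3 samples, 2 features, 2 annotators, one missing annotation."""
    X = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.5]])
    Y = np.array([[1.0, 1.2], [2.0, np.nan], [3.0, 2.8]])
    mask = np.isfinite(Y)
    return MultiAnnotatorDataset(X, Y, mask, ["f1", "f2"], ["a1", "a2"], "attr")
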
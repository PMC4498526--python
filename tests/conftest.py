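import numpy as np
import pytest

from lhda import LHDAConfig, LabeledDataset, generate_blobs


@pytest.fixture
def tiny_config():
    return LHDAConfig(k=2, max_iter=20)


@pytest.fixture
def blob_dataset():
    """Well-separated two-class Gaussian blobs with two noise features."""
    return generate_blobs(
        n_per_class=12, informative_dims=1, noise_dim=2, separation=8.0, seed=3
    )


@pytest.fixture
def three_class_dataset():
    return generate_blobs(
        n_per_class=10, n_classes=3, informative_dims=2, noise_dim=1,
        separation=6.0, seed=5,
    )


def random_dataset(rng, n_per_class=6, n_classes=2, d=4):
    """Unstructured random labeled data (no class signal)."""
    n = n_per_class * n_classes
    X = rng.normal(size=(n, d))
    y = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    return LabeledDataset(X, y)
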
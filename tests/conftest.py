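import numpy as np
import pytest

from thncdf.datatypes import DiseaseProfileMatrix, FingerprintSet, InteractionMatrix
from thncdf.synthetic import SynthConfig, generate


@pytest.fixture(scope="session")
def synth_default():
    """Default planted-block dataset, seed 0 (shared, read-only)."""
    return generate(SynthConfig(seed=0))


@pytest.fixture
def tiny_interactions():
    Y = np.array([[1, 0, 1], [0, 1, 1]])
    return InteractionMatrix(["D1", "D2"], ["hsa1", "hsa2", "hsa3"], Y)


@pytest.fixture
def tiny_fingerprints():
    bits = np.zeros((2, 166), dtype=int)
    bits[0, [1, 2]] = 1
    bits[1, [1, 3]] = 1
    return FingerprintSet(["D1", "D2"], bits)


@pytest.fixture
def tiny_disease_profiles():
    P = np.array([[1, 0], [1, 1], [0, 1]])
    return DiseaseProfileMatrix(["hsa1", "hsa2", "hsa3"], ["s1", "s2"], P)


def separable_dataset(n=200, n_features=10, seed=0, gap=2.0):
    """Two well-separated Gaussian blobs with binary labels."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, n_features)) * 0.5
    X[y == 1, :3] += gap
    perm = rng.permutation(n)
    return X[perm], y[perm]
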
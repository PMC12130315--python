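import numpy as np
import pytest

from modfuse import GeneratorConfig, generate_world
from modfuse.pipeline import modality_distance_matrices


@pytest.fixture(scope="session")
def small_world():
    """60 entities, 3 clusters, mild noise, default (partial) coverage."""
    return generate_world(GeneratorConfig(n_entities=60, n_clusters=3,
                                          noise_level=0.05, seed=11))


@pytest.fixture(scope="session")
def clean_world():
    """Zero noise, full coverage: planted structure is exact."""
    return generate_world(GeneratorConfig(n_entities=48, n_clusters=4,
                                          noise_level=0.0, coverage=1.0, seed=5))


@pytest.fixture(scope="session")
def clean_distances(clean_world):
    return modality_distance_matrices(clean_world)


@pytest.fixture(scope="session")
def small_distances(small_world):
    return modality_distance_matrices(small_world)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
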
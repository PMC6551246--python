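import numpy as np
import pytest

from scpowerkit import SimulationParams, generate_dataset, preprocess


@pytest.fixture(scope="session")
def small_params():
    # scaled-down but well-separated: 5 types, strong markers
    return SimulationParams(n_cells=200, proportions=(0.1, 0.2, 0.2, 0.2, 0.3),
                            n_genes=500, n_markers_per_type=20, fold_change=8.0,
                            seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return generate_dataset(small_params)


@pytest.fixture(scope="session")
def small_embedding(small_dataset):
    return preprocess(small_dataset)


@pytest.fixture(scope="session")
def two_blob_embedding():
    """Two tight, far-apart gaussian blobs in 2-D (20 + 30 points)."""
    rng = np.random.default_rng(3)
    a = rng.normal([0, 0], 0.1, size=(20, 2))
    b = rng.normal([10, 10], 0.1, size=(30, 2))
    labels = np.array([1] * 20 + [2] * 30)
    return np.vstack([a, b]), labels
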
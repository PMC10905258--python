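import numpy as np
import pytest

from batcheval import ClassifierConfig, SimConfig, prepare_embeddings, simulate_batches


@pytest.fixture(scope="session")
def strong_effect_dataset():
    """Three batches with a strong multiplicative batch effect; PCA attached."""
    ds = simulate_batches(SimConfig(n_batches=3, cells_per_batch=120,
                                    n_genes=150, batch_effect=2.0, seed=7))
    prepare_embeddings(ds, n_components=30, seed=0, with_umap=False)
    return ds


@pytest.fixture(scope="session")
def null_dataset():
    """Two exchangeable batches: no batch shift, equal depth; PCA attached."""
    ds = simulate_batches(SimConfig(n_batches=2, cells_per_batch=150,
                                    n_genes=150, batch_effect=0.0,
                                    libsize_factor=(1.0, 1.0), seed=11))
    prepare_embeddings(ds, n_components=30, seed=0, with_umap=False)
    return ds


@pytest.fixture
def quick_classifier_config():
    """Compact network on PCA features; converges on the synthetic fixtures."""
    return ClassifierConfig(hidden_units=64, epochs=100, seed=0, features="pca")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
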
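import numpy as np
import pytest

import deephier as dh
from deephier.seqio import LEVELS


@pytest.fixture(scope="session")
def toy_dataset():
    """Small noiseless synthetic dataset: (2,2,2) tree, 6 sequences/class."""
    spec = dh.build_spec(2, 2, 2, motif_lengths=(8, 6, 5), seq_length=120, seed=5)
    data = dh.simulate_sequences(spec, 6, mutation_rate=0.0, seed=5)
    return data


@pytest.fixture(scope="session")
def tiny_model_setup():
    """A small untrained model plus an encoded batch, for shape/grad tests."""
    spec = dh.build_spec(3, 2, 2, motif_lengths=(8, 6, 5), seq_length=60, seed=3)
    data = dh.simulate_sequences(spec, 3, mutation_rate=0.05, seed=3)
    ds = data.dataset
    config = dh.ModelConfig(
        n_classes={lvl: ds.hierarchy.n_classes(lvl) for lvl in LEVELS},
        kernel_sizes=(5, 7),
        filters_per_kernel=4,
        embed_dim=6,
        classifier_hidden=5,
        encoded_length=70,
    )
    model = dh.DeepHierNet(config, seed=1)
    X = ds.encode(70)
    labels = {lvl: ds.label_indices(lvl) for lvl in LEVELS}
    return model, ds, X, labels
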
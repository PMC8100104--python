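"""The canonical synthetic benchmark: one call that runs the whole method.

The benchmark conditions are a 3-family x 2-subfamily x 2-sub-subfamily
tree (12 leaf classes), 40 sequences per leaf class of length 200 with a
5% per-position motif mutation rate, split 0.8/0.1/0.1 per subfamily.  The
model is a desk-scale instance of the architecture (3 kernel sizes, 64
filters each, 30-dimensional embedding) trained with the three-phase
curriculum for 3/3/40 epochs.  One run takes about a minute on a single
CPU core.

Everything is deterministic given ``seed``; the data, split and parameter
initialization each use a distinct stream derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import ami_curve, silhouette_by_level
from .losses import default_phases
from .model import DeepHierNet, ModelConfig
from .search import build_database, retrieval_accuracy
from .seqio import LEVELS, SequenceDataset
from .synthetic import build_spec, simulate_sequences
from .training import (
    TrainReport,
    TrainRunConfig,
    evaluate_dataset_accuracy,
    split_dataset,
    train,
)

#: Benchmark data conditions.
N_FAMILIES, N_SUBFAM_PER, N_SUBSUB_PER = 3, 2, 2
N_PER_CLASS = 40
SEQ_LENGTH = 200
MUTATION_RATE = 0.05
MAX_LEN = 220

#: True class counts per level for the benchmark tree.
TRUE_COUNTS = {"family": 3, "subfamily": 6, "subsubfamily": 12}


def benchmark_dataset(seed: int):
    """Simulate the benchmark dataset and its train/validation/test split."""
    spec = build_spec(
        N_FAMILIES, N_SUBFAM_PER, N_SUBSUB_PER,
        seq_length=SEQ_LENGTH, seed=seed,
    )
    data = simulate_sequences(spec, N_PER_CLASS, MUTATION_RATE, seed=seed + 1)
    tr, va, te = split_dataset(data.dataset, seed=seed + 2)
    return data, tr, va, te


def benchmark_run_config(
    dataset: SequenceDataset,
    seed: int,
    no_center_loss: bool = False,
) -> TrainRunConfig:
    """The desk-scale training configuration used throughout the benchmark."""
    mc = ModelConfig(
        n_classes={lvl: dataset.hierarchy.n_classes(lvl) for lvl in LEVELS},
        kernel_sizes=(6, 10, 14),
        filters_per_kernel=64,
        encoded_length=MAX_LEN,
    )
    return TrainRunConfig(
        model=mc,
        phases=default_phases((3, 3, 40)),
        learning_rate=0.005,
        batch_size=32,
        seed=seed,
        max_len=MAX_LEN,
        weight_decay=5e-4,
        augment_rate=0.03,
        no_center_loss=no_center_loss,
    )


@dataclass
class BenchmarkResult:
    model: DeepHierNet
    report: TrainReport
    test_accuracy: dict[str, float]
    silhouette: dict[str, float]
    ami_argmax_k: dict[str, int]
    retrieval: dict[str, float]
    test_embeddings: np.ndarray
    test_labels: dict[str, list]


def run_benchmark(seed: int, no_center_loss: bool = False) -> BenchmarkResult:
    """Train on the benchmark and evaluate every headline quantity.

    Returns held-out classification accuracy per level, silhouette scores of
    the test embeddings against true labels, the argmax-k of the AMI-vs-k
    curve (ward clustering, k = 2, 5, 8, ... up to the test-set size), and
    top-1 retrieval accuracy of test queries against the training database.
    """
    _, tr, va, te = benchmark_dataset(seed)
    run = benchmark_run_config(tr, seed, no_center_loss=no_center_loss)
    model, report = train(run, tr, va)

    acc = {
        lvl: evaluate_dataset_accuracy(model, te, lvl, MAX_LEN)
        for lvl in model.config.levels
    }
    emb = model.embed_sequences(te.encode(MAX_LEN))
    labs = {lvl: te.labels_at(lvl) for lvl in LEVELS}
    sil = silhouette_by_level(emb, labs)
    curve = ami_curve(emb, labs, k_from=2, k_to=len(te), step=3)
    argmax = {lvl: curve.argmax_k(lvl) for lvl in LEVELS}
    db = build_database(model, tr, MAX_LEN)
    retr = {
        lvl: retrieval_accuracy(db, model, te, lvl, MAX_LEN) for lvl in LEVELS
    }
    return BenchmarkResult(
        model=model,
        report=report,
        test_accuracy=acc,
        silhouette=sil,
        ami_argmax_k=argmax,
        retrieval=retr,
        test_embeddings=emb,
        test_labels=labs,
    )
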
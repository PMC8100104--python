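"""Training objective: per-level softmax cross-entropy, per-level center
loss, their weighted combination, and whole-dataset center updates.

The center loss for one hierarchy level is

    L_C = sum_i || e_i - mu_{y_i} ||_2^2

a batch **sum** of squared Euclidean distances between each embedding e_i
and the mean embedding mu of its class, computed over the entire training
set (not per mini-batch).  Cross-entropy is a batch **mean**; both
conventions are fixed so the loss weights are interpretable.

The total objective is the weighted combination

    L = sum_l w_S[l] * L_S[l]  +  lambda_C * sum_l w_C[l] * L_C[l]

where l ranges over the hierarchy levels.  The three curriculum phases
shift weight mass from the family level down to the sub-subfamily level
while raising lambda_C (defaults in DEFAULT_PHASES).

Centers are treated as constants inside a batch: no gradient flows into
mu.  They are refreshed by recomputing per-class means of the whole
training set once per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DeepHierNet
from .seqio import LEVELS


class LossError(ValueError):
    pass


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def cross_entropy_level(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log softmax probability of the true class."""
    labels = np.asarray(labels)
    if logits.shape[0] != labels.shape[0]:
        raise LossError("logits and labels must share the batch dimension")
    if labels.min() < 0 or labels.max() >= logits.shape[1]:
        raise LossError("label index out of range")
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    nll = logsumexp - z[np.arange(len(labels)), labels]
    return float(nll.mean())


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean NLL)/d(logits) = (softmax - onehot) / batch."""
    p = softmax(logits)
    p[np.arange(len(labels)), labels] -= 1.0
    return p / len(labels)


@dataclass
class ClassCenters:
    """Per-level map class index -> mean embedding (rows of a (C, d) array)."""

    centers: dict[str, np.ndarray]

    def at(self, level: str) -> np.ndarray:
        if level not in self.centers:
            raise LossError(f"no centers for level {level!r}")
        return self.centers[level]


def center_loss_level(
    embeddings: np.ndarray, labels: np.ndarray, centers: np.ndarray
) -> float:
    """Sum over the batch of squared Euclidean distance to the own-class center."""
    labels = np.asarray(labels)
    if labels.max() >= centers.shape[0]:
        raise LossError(
            f"missing center for class index {int(labels.max())}"
        )
    diff = embeddings - centers[labels]
    return float(np.sum(diff * diff))


def center_loss_grad(
    embeddings: np.ndarray, labels: np.ndarray, centers: np.ndarray
) -> np.ndarray:
    """d(center loss)/d(embeddings) = 2 (e_i - mu_{y_i}); centers held constant."""
    return 2.0 * (embeddings - centers[np.asarray(labels)])


@dataclass
class PhaseConfig:
    """Loss weights and epoch budget for one curriculum phase."""

    name: str
    lambda_c: float
    omega_s: dict[str, float]  # level -> cross-entropy weight
    omega_c: dict[str, float]  # level -> center-loss weight
    epochs: int = 30

    def __post_init__(self) -> None:
        if self.lambda_c < 0:
            raise LossError("lambda_c must be >= 0")
        for w in list(self.omega_s.values()) + list(self.omega_c.values()):
            if w < 0:
                raise LossError("loss weights must be >= 0")


def default_phases(epochs: tuple[int, int, int] = (30, 30, 40)) -> list[PhaseConfig]:
    """The three-phase curriculum defaults.

    Phase 1 concentrates weight on the family level with a small center-loss
    multiplier; later phases shift mass to the subfamily and sub-subfamily
    levels while raising lambda_C (0.01 -> 0.3 -> 0.5).
    """
    return [
        PhaseConfig(
            name="family",
            lambda_c=0.01,
            omega_s={"family": 0.8, "subfamily": 0.15, "subsubfamily": 0.05},
            omega_c={"family": 0.8, "subfamily": 0.15, "subsubfamily": 0.05},
            epochs=epochs[0],
        ),
        PhaseConfig(
            name="subfamily",
            lambda_c=0.3,
            omega_s={"family": 0.1, "subfamily": 0.8, "subsubfamily": 0.1},
            omega_c={"family": 0.1, "subfamily": 0.8, "subsubfamily": 0.1},
            epochs=epochs[1],
        ),
        PhaseConfig(
            name="subsubfamily",
            lambda_c=0.5,
            omega_s={"family": 0.1, "subfamily": 0.25, "subsubfamily": 0.65},
            omega_c={"family": 0.1, "subfamily": 0.15, "subsubfamily": 0.75},
            epochs=epochs[2],
        ),
    ]


def total_loss(
    ce_losses: dict[str, float],
    center_losses: dict[str, float],
    phase: PhaseConfig,
) -> float:
    """Weighted combination of per-level cross-entropy and center losses."""
    for d in (ce_losses, center_losses):
        for level, v in d.items():
            if not np.isfinite(v):
                raise LossError(f"non-finite loss component at level {level!r}")
            if v < 0:
                raise LossError(f"negative loss component at level {level!r}")
    ce = sum(phase.omega_s.get(l, 0.0) * v for l, v in ce_losses.items())
    cl = sum(phase.omega_c.get(l, 0.0) * v for l, v in center_losses.items())
    return float(ce + phase.lambda_c * cl)


def update_centers(
    model: DeepHierNet,
    X: np.ndarray,
    labels: dict[str, np.ndarray],
    n_classes: dict[str, int],
    batch_size: int = 128,
) -> ClassCenters:
    """Recompute per-class mean embeddings over the whole training set.

    Every class at every level must have at least one member; a class with
    zero members would leave its center undefined.
    """
    emb = model.embed_sequences(X, batch_size=batch_size)
    centers: dict[str, np.ndarray] = {}
    for level, lab in labels.items():
        C = n_classes[level]
        counts = np.bincount(lab, minlength=C)
        if np.any(counts == 0):
            empty = np.nonzero(counts == 0)[0]
            raise LossError(
                f"class index {empty.tolist()} at level {level!r} has no training members"
            )
        sums = np.zeros((C, emb.shape[1]))
        np.add.at(sums, lab, emb)
        centers[level] = sums / counts[:, None]
    return ClassCenters(centers)
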
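"""Three-phase curriculum training, stratified splitting, and evaluation.

Training proceeds in three phases ordered coarse to fine: a family-focused
phase, a subfamily-focused phase and a sub-subfamily-focused phase, each
with its own loss weights (see losses.default_phases).  Class centers are
initialized from one full forward pass before the first phase and
recomputed from the whole training set after every epoch.  The returned
model is the checkpoint with the best validation accuracy at the finest
configured level.

Splitting is stratified per subfamily with an exact floor-plus-largest-
remainder allocation, so a class of 10 under ratios (0.8, 0.1, 0.1) yields
an 8/1/1 partition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import losses as L
from .losses import ClassCenters, PhaseConfig, default_phases
from .model import DeepHierNet, ModelConfig
from .seqio import LEVELS, SequenceDataset

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainRunConfig:
    """Everything needed to reproduce a training run."""

    model: ModelConfig
    phases: list[PhaseConfig] = field(default_factory=default_phases)
    learning_rate: float = 0.001
    batch_size: int = 64
    seed: int = 0
    max_len: int = 1000
    weight_decay: float = 0.0     # L2 penalty on conv and embedding weights
    augment_rate: float = 0.0     # per-position random substitution rate on training batches
    center_update: str = "step"   # "step": refresh class means after every optimizer
                                  # step from cached whole-dataset embeddings;
                                  # "epoch": recompute once per epoch only
    final_average_k: int = 10     # tail-average the last k epoch-end parameter
                                  # states of the final phase (0 disables); the
                                  # average replaces the best checkpoint only if
                                  # it validates at least as well
    lr_schedule: str = "constant" # "constant" or "cosine" (per-phase decay to
                                  # one tenth of the base rate)
    no_center_loss: bool = False  # ablation: lambda_C forced to 0 in every phase
    single_branch: bool = False   # ablation: only the sub-subfamily classifier head

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if any(p.epochs < 0 for p in self.phases):
            raise ValueError("epoch budgets must be >= 0")
        if self.center_update not in ("step", "epoch"):
            raise ValueError("center_update must be 'step' or 'epoch'")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        if not self.single_branch and len(self.phases) != 3:
            raise ValueError("expected exactly 3 phases")

    def effective_phases(self) -> list[PhaseConfig]:
        if self.no_center_loss:
            return [
                PhaseConfig(p.name, 0.0, dict(p.omega_s), dict(p.omega_c), p.epochs)
                for p in self.phases
            ]
        return self.phases


@dataclass
class EpochRecord:
    phase: str
    epoch: int
    total_loss: float
    ce_losses: dict[str, float]
    center_losses: dict[str, float]
    val_accuracy: dict[str, float]


@dataclass
class TrainReport:
    records: list[EpochRecord] = field(default_factory=list)
    best_checkpoint: tuple[str, int] | None = None
    best_val_accuracy: float = -1.0

    def losses_by_phase(self, phase: str) -> list[float]:
        return [r.total_loss for r in self.records if r.phase == phase]


def split_dataset(
    dataset: SequenceDataset,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[SequenceDataset, SequenceDataset, SequenceDataset]:
    """Stratified train/validation/test split per subfamily class.

    Within each subfamily, members are shuffled and allocated by floor of
    ratio*n with the remainder going to the splits with the largest
    fractional parts (ties favour the earlier split).  The three outputs
    share the full dataset's hierarchy table so class indexing stays
    consistent across splits.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(dataset.sequences):
        groups.setdefault(s.label.subfamily, []).append(i)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    n_nonzero = sum(1 for r in ratios if r > 0)
    for sub in sorted(groups):
        idx = np.array(groups[sub])
        if len(idx) < n_nonzero:
            raise TrainingError(
                f"subfamily {sub!r} has {len(idx)} members; too few for a "
                f"{'/'.join(str(r) for r in ratios)} split"
            )
        rng.shuffle(idx)
        counts = _allocate(len(idx), ratios)
        lo = 0
        for part, c in zip(parts, counts):
            part.extend(int(j) for j in idx[lo : lo + c])
            lo += c
    out = []
    for part in parts:
        seqs = [dataset.sequences[i] for i in sorted(part)]
        out.append(SequenceDataset(seqs, dataset.hierarchy))
    return tuple(out)


def _allocate(n: int, ratios: tuple[float, ...]) -> list[int]:
    exact = [r * n for r in ratios]
    counts = [int(np.floor(e)) for e in exact]
    # guarantee each nonzero-ratio split at least one member
    for i, r in enumerate(ratios):
        if r > 0 and counts[i] == 0:
            counts[i] = 1
    remainder = n - sum(counts)
    if remainder < 0:
        # steal back from the largest split
        while remainder < 0:
            j = int(np.argmax(counts))
            counts[j] -= 1
            remainder += 1
    else:
        fracs = sorted(
            range(len(ratios)), key=lambda i: (-(exact[i] - np.floor(exact[i])), i)
        )
        for i in range(remainder):
            counts[fracs[i % len(fracs)]] += 1
    return counts


def _augment_substitutions(
    X: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Label-preserving augmentation: substitute residues at random positions.

    Each encoded (non-padding) position is replaced by a uniformly random
    residue with probability `rate`, emulating point substitutions.  Padding
    and unknown-residue rows are left untouched.
    """
    X = X.copy()
    valid = X.sum(axis=2) > 0  # (B, L)
    hit = (rng.random(valid.shape) < rate) & valid
    b, l = np.nonzero(hit)
    if len(b):
        X[b, l, :] = 0.0
        X[b, l, rng.integers(X.shape[2], size=len(b))] = 1.0
    return X


class Adam:
    """Standard Adam optimizer on a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _SmoothedSelector:
    """Pick the checkpoint maximizing a moving average of validation accuracy.

    Each epoch's score is the mean of its raw validation accuracy and that of
    its immediate neighbours (window 3; boundary epochs use the epochs that
    exist).  Ties go to the later epoch.  Only a 3-deep buffer of parameter
    states is retained.
    """

    def __init__(self, window: int, initial_state: dict[str, np.ndarray]) -> None:
        assert window == 3, "only a 3-epoch window is implemented"
        self._buf: list[tuple[float, dict[str, np.ndarray], tuple[str, int]]] = []
        self._best_score = -np.inf
        self._best = (initial_state, -1.0, None)

    def _consider(self, center: int) -> None:
        vals = [v for v, _, _ in self._buf]
        score = float(np.mean(vals))
        raw, state, cid = self._buf[center]
        if score >= self._best_score:
            self._best_score = score
            self._best = (state, raw, cid)

    def add(self, val_acc: float, state: dict[str, np.ndarray],
            checkpoint_id: tuple[str, int]) -> None:
        self._buf.append((val_acc, state, checkpoint_id))
        if len(self._buf) > 3:
            self._buf.pop(0)
        if len(self._buf) >= 2:
            # the element one behind the newest now has its full window
            self._consider(len(self._buf) - 2)

    def finish(self) -> None:
        if len(self._buf) == 1:
            self._consider(0)
        elif len(self._buf) >= 2:
            # last epoch: window is itself and its predecessor
            self._buf.pop(0) if len(self._buf) == 3 else None
            self._consider(len(self._buf) - 1)

    def best(self) -> tuple[dict[str, np.ndarray], float, tuple[str, int] | None]:
        return self._best


def _centers_from_cache(
    emb_cache: np.ndarray,
    labels: dict[str, np.ndarray],
    n_classes: dict[str, int],
) -> ClassCenters:
    centers: dict[str, np.ndarray] = {}
    for level, lab in labels.items():
        C = n_classes[level]
        counts = np.bincount(lab, minlength=C)
        sums = np.zeros((C, emb_cache.shape[1]))
        np.add.at(sums, lab, emb_cache)
        centers[level] = sums / np.maximum(counts, 1)[:, None]
    return ClassCenters(centers)


def _prepare(dataset: SequenceDataset, levels: tuple[str, ...], max_len: int):
    X = dataset.encode(max_len)
    labels = {lvl: dataset.label_indices(lvl) for lvl in LEVELS}
    return X, labels


def train(
    run_config: TrainRunConfig,
    train_set: SequenceDataset,
    val_set: SequenceDataset,
) -> tuple[DeepHierNet, TrainReport]:
    """Run the three-phase curriculum and return the best checkpoint.

    Center losses are computed at all three hierarchy levels even in the
    single-branch ablation; only the classifier heads differ.  The model
    returned is a copy of the parameters at the epoch with the highest
    validation accuracy at the finest configured level (initial parameters
    if every epoch budget is zero).
    """
    cfg = run_config
    model = DeepHierNet(cfg.model, seed=cfg.seed)
    levels = model.config.levels
    finest = levels[-1]
    # centers are kept at all three levels even when only one branch exists
    hier = train_set.hierarchy
    center_n_classes = {lvl: hier.n_classes(lvl) for lvl in LEVELS}

    Xtr, ytr = _prepare(train_set, levels, cfg.max_len)
    Xva, yva = _prepare(val_set, levels, cfg.max_len)

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.params, cfg.learning_rate)
    report = TrainReport()

    # Checkpoint selection smooths the (small-sample, hence noisy) validation
    # trajectory with a 3-epoch moving average so a lone spike cannot win;
    # ties go to the later epoch, whose parameters are more converged.
    selector = _SmoothedSelector(window=3, initial_state=model.state_copy())

    centers = L.update_centers(model, Xtr, ytr, center_n_classes,
                               batch_size=cfg.batch_size)
    # Cached whole-dataset embeddings back the per-step center refresh: after
    # each optimizer step the current batch's rows are replaced and the class
    # means recomputed, so centers track the parameters within an epoch.
    emb_cache = model.embed_sequences(Xtr, batch_size=cfg.batch_size)

    n = Xtr.shape[0]
    phases = cfg.effective_phases()
    final_phase = phases[-1] if phases else None
    tail_states: list[dict[str, np.ndarray]] = []
    for phase in phases:
        for epoch in range(phase.epochs):
            if cfg.lr_schedule == "cosine" and phase.epochs > 1:
                frac = epoch / (phase.epochs - 1)
                opt.lr = cfg.learning_rate * (0.1 + 0.45 * (1 + np.cos(np.pi * frac)))
            order = rng.permutation(n)
            ep_ce = {lvl: 0.0 for lvl in LEVELS}
            ep_cl = {lvl: 0.0 for lvl in LEVELS}
            nb = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                X = Xtr[idx]
                if cfg.augment_rate > 0:
                    X = _augment_substitutions(X, cfg.augment_rate, rng)
                emb, logits, cache = model.forward(X, with_cache=True)
                dlogits = {}
                ce_losses = {}
                for lvl in levels:
                    lab = ytr[lvl][idx]
                    ce_losses[lvl] = L.cross_entropy_level(logits[lvl], lab)
                    dlogits[lvl] = (
                        phase.omega_s.get(lvl, 0.0)
                        * L.cross_entropy_grad(logits[lvl], lab)
                    )
                # Center terms enter the training objective as per-sample
                # means so their gradient scale is batch-size-independent and
                # commensurate with the batch-mean cross-entropy.
                cl_losses = {}
                dembed = np.zeros_like(emb)
                for lvl in LEVELS:
                    mu = centers.at(lvl)
                    lab = ytr[lvl][idx]
                    cl_losses[lvl] = L.center_loss_level(emb, lab, mu) / len(idx)
                    if phase.lambda_c > 0:
                        dembed += (
                            phase.lambda_c
                            * phase.omega_c.get(lvl, 0.0)
                            * L.center_loss_grad(emb, lab, mu)
                            / len(idx)
                        )
                grads = model.backward(cache, dlogits, dembed)
                if cfg.weight_decay > 0:
                    for name in model.params:
                        if name.startswith("conv_W") or name == "embed_W":
                            grads[name] += 2 * cfg.weight_decay * model.params[name]
                opt.step(model.params, grads)
                if cfg.center_update == "step":
                    emb_cache[idx] = emb
                    centers = _centers_from_cache(
                        emb_cache, ytr, center_n_classes
                    )
                total = L.total_loss(ce_losses, cl_losses, phase)
                if not np.isfinite(total):
                    raise TrainingError(
                        f"non-finite loss in phase {phase.name!r} epoch {epoch}"
                    )
                for lvl in LEVELS:
                    ep_ce[lvl] = ep_ce.get(lvl, 0.0) + ce_losses.get(lvl, 0.0)
                    ep_cl[lvl] += cl_losses[lvl]
                nb += 1
            emb_cache = model.embed_sequences(Xtr, batch_size=cfg.batch_size)
            centers = _centers_from_cache(emb_cache, ytr, center_n_classes)
            ep_ce = {k: v / nb for k, v in ep_ce.items() if k in levels}
            ep_cl = {k: v / nb for k, v in ep_cl.items()}
            val_acc = {
                lvl: evaluate_accuracy(model, Xva, yva[lvl], lvl,
                                       batch_size=cfg.batch_size)
                for lvl in levels
            }
            rec = EpochRecord(
                phase=phase.name,
                epoch=epoch,
                total_loss=L.total_loss(ep_ce, {k: v for k, v in ep_cl.items()}, phase),
                ce_losses=ep_ce,
                center_losses=ep_cl,
                val_accuracy=val_acc,
            )
            report.records.append(rec)
            logger.info(
                "phase %s epoch %d: loss %.4f val acc %s",
                phase.name, epoch, rec.total_loss,
                {k: round(v, 3) for k, v in val_acc.items()},
            )
            selector.add(val_acc[finest], model.state_copy(), (phase.name, epoch))
            if cfg.final_average_k > 0 and phase is final_phase:
                tail_states.append(model.state_copy())
                if len(tail_states) > cfg.final_average_k:
                    tail_states.pop(0)
    selector.finish()
    best_state, best_acc, best_id = selector.best()
    if tail_states:
        avg_state = {
            k: np.mean([s[k] for s in tail_states], axis=0) for k in tail_states[0]
        }
        model.load_state(avg_state)
        avg_acc = evaluate_accuracy(model, Xva, yva[finest], finest,
                                    batch_size=cfg.batch_size)
        if avg_acc >= best_acc:
            best_acc = avg_acc
            best_state = avg_state
            best_id = ("tail-average", len(tail_states))
    model.load_state(best_state)
    report.best_checkpoint = best_id
    report.best_val_accuracy = best_acc
    return model, report


def evaluate_accuracy(
    model: DeepHierNet,
    X: np.ndarray,
    labels: np.ndarray,
    level: str,
    batch_size: int = 128,
) -> float:
    """Fraction of inputs whose argmax logit matches the true class at a level."""
    if X.shape[0] == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    correct = 0
    for i in range(0, X.shape[0], batch_size):
        feats = model.extract_features(X[i : i + batch_size])
        emb = model.embed(feats)
        logits = model.classify(emb, level)
        correct += int(np.sum(logits.argmax(axis=1) == labels[i : i + batch_size]))
    return correct / X.shape[0]


def evaluate_dataset_accuracy(
    model: DeepHierNet, dataset: SequenceDataset, level: str, max_len: int = 1000
) -> float:
    """Convenience wrapper taking a SequenceDataset instead of arrays."""
    X = dataset.encode(max_len)
    labels = dataset.label_indices(level)
    return evaluate_accuracy(model, X, labels, level)
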
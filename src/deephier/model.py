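"""The hierarchical embedding network.

Architecture: a bank of one-dimensional convolutional filters of several
kernel sizes scans the one-hot sequence matrix; each filter's ReLU
responses are reduced by one-max pooling to a single "motif presence"
value; the pooled values are concatenated, projected linearly to a
d-dimensional vector and L2-normalized so every embedding lies on the unit
hypersphere.  One small MLP classifier branch per hierarchy level (family,
subfamily, sub-subfamily) is attached to the embedding.

The network is implemented directly on numpy with explicit forward /
backward passes.  Convolution is realized as a sliding-window matrix
product; one-max pooling backpropagates only through the argmax position
of each filter.  Gradients through the L2 normalization use the exact
Jacobian  (I - e e^T) / ||z||  of z -> z/||z||.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import LEVELS

DEFAULT_KERNEL_SIZES = (8, 12, 16, 20, 24, 28, 32, 36)


class ModelError(ValueError):
    pass


class DegenerateEmbeddingError(ModelError):
    """Pre-normalization vector has near-zero norm; normalizing would amplify noise."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 8 kernel sizes from 8 to
    36, 256 filters each (2048 pooled features), a 30-dimensional
    embedding, classifier branches with 15 hidden units and L2 weight
    penalty 5e-4, inputs padded to length 1000 over the 20-letter alphabet.
    """

    n_classes: dict[str, int]  # level -> class count; defines the branches
    kernel_sizes: tuple[int, ...] = DEFAULT_KERNEL_SIZES
    filters_per_kernel: int = 256
    embed_dim: int = 30
    classifier_hidden: int = 15
    classifier_l2: float = 5e-4
    encoded_length: int = 1000
    alphabet_size: int = 20
    embed_bias: bool = True

    def __post_init__(self) -> None:
        self.kernel_sizes = tuple(int(k) for k in self.kernel_sizes)
        if min(self.kernel_sizes) < 1 or self.filters_per_kernel < 1:
            raise ModelError("kernel sizes and filter counts must be positive")
        if max(self.kernel_sizes) > self.encoded_length:
            raise ModelError("max kernel size must not exceed the encoded length")
        if self.embed_dim < 1 or self.classifier_hidden < 1:
            raise ModelError("embed_dim and classifier_hidden must be positive")
        for level, n in self.n_classes.items():
            if level not in LEVELS:
                raise ModelError(f"unknown hierarchy level {level!r}")
            if n < 2:
                raise ModelError(f"level {level!r} needs >= 2 classes, got {n}")

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(l for l in LEVELS if l in self.n_classes)

    @property
    def feature_dim(self) -> int:
        return self.filters_per_kernel * len(self.kernel_sizes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel_sizes"] = list(self.kernel_sizes)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelConfig":
        d = dict(d)
        d["kernel_sizes"] = tuple(d["kernel_sizes"])
        return cls(**d)


@dataclass
class ForwardCache:
    """Intermediate values retained for the backward pass."""

    X: np.ndarray
    windows: dict[int, np.ndarray]
    relu_mask: dict[int, np.ndarray]
    argmax: dict[int, np.ndarray]
    features: np.ndarray
    pre_norm: np.ndarray
    norms: np.ndarray
    embeddings: np.ndarray
    hidden: dict[str, np.ndarray]
    hidden_mask: dict[str, np.ndarray]


class DeepHierNet:
    """Multi-kernel motif CNN + unit-sphere embedding + per-level classifiers."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        A = config.alphabet_size
        F = config.filters_per_kernel
        # He initialization for the ReLU conv/MLP layers, Glorot for linear outputs.
        for k in config.kernel_sizes:
            fan_in = k * A
            self.params[f"conv_W{k}"] = (
                rng.standard_normal((fan_in, F)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float64)
            self.params[f"conv_b{k}"] = np.zeros(F)
        D = config.feature_dim
        d = config.embed_dim
        self.params["embed_W"] = (
            rng.standard_normal((D, d)) * np.sqrt(1.0 / D)
        ).astype(np.float64)
        if config.embed_bias:
            self.params["embed_b"] = np.zeros(d)
        H = config.classifier_hidden
        for level in config.levels:
            C = config.n_classes[level]
            self.params[f"{level}_W1"] = (
                rng.standard_normal((d, H)) * np.sqrt(2.0 / d)
            ).astype(np.float64)
            self.params[f"{level}_b1"] = np.zeros(H)
            self.params[f"{level}_W2"] = (
                rng.standard_normal((H, C)) * np.sqrt(1.0 / H)
            ).astype(np.float64)
            self.params[f"{level}_b2"] = np.zeros(C)

    # ------------------------------------------------------------------ forward

    def extract_features(
        self, X: np.ndarray, cache: ForwardCache | None = None
    ) -> np.ndarray:
        """Conv + ReLU + one-max pooling, concatenated over kernel sizes.

        X: (batch, L, A) one-hot input.  Output: (batch, feature_dim), >= 0.
        """
        cfg = self.config
        if X.ndim != 3 or X.shape[1] != cfg.encoded_length or X.shape[2] != cfg.alphabet_size:
            raise ModelError(
                f"expected input of shape (n, {cfg.encoded_length}, "
                f"{cfg.alphabet_size}), got {X.shape}"
            )
        B = X.shape[0]
        pooled = []
        for k in cfg.kernel_sizes:
            # (B, P, k, A) windows -> (B, P, k*A) then matmul with (k*A, F)
            w = sliding_window_view(X, (k, cfg.alphabet_size), axis=(1, 2))[:, :, 0]
            wf = np.ascontiguousarray(w).reshape(B, -1, k * cfg.alphabet_size)
            Z = wf @ self.params[f"conv_W{k}"] + self.params[f"conv_b{k}"]
            mask = Z > 0
            A_ = np.where(mask, Z, 0.0)
            am = A_.argmax(axis=1)  # (B, F)
            p = np.take_along_axis(A_, am[:, None, :], axis=1)[:, 0, :]
            pooled.append(p)
            if cache is not None:
                cache.windows[k] = wf
                cache.relu_mask[k] = mask
                cache.argmax[k] = am
        feats = np.concatenate(pooled, axis=1)
        if cache is not None:
            cache.features = feats
        return feats

    def embed(
        self, features: np.ndarray, cache: ForwardCache | None = None
    ) -> np.ndarray:
        """Linear projection to d dims followed by L2 normalization."""
        cfg = self.config
        if features.shape[1] != cfg.feature_dim:
            raise ModelError(
                f"feature dim {features.shape[1]} != configured {cfg.feature_dim}"
            )
        z = features @ self.params["embed_W"]
        if cfg.embed_bias:
            z = z + self.params["embed_b"]
        norms = np.linalg.norm(z, axis=1)
        if np.any(norms < 1e-12):
            raise DegenerateEmbeddingError(
                "pre-normalization embedding has near-zero norm"
            )
        e = z / norms[:, None]
        if cache is not None:
            cache.pre_norm = z
            cache.norms = norms
            cache.embeddings = e
        return e

    def classify(
        self, embeddings: np.ndarray, level: str, cache: ForwardCache | None = None
    ) -> np.ndarray:
        """Logits of the MLP branch for one hierarchy level."""
        if level not in self.config.levels:
            raise ModelError(f"branch not present for level {level!r}")
        h_pre = embeddings @ self.params[f"{level}_W1"] + self.params[f"{level}_b1"]
        mask = h_pre > 0
        h = np.where(mask, h_pre, 0.0)
        logits = h @ self.params[f"{level}_W2"] + self.params[f"{level}_b2"]
        if cache is not None:
            cache.hidden[level] = h
            cache.hidden_mask[level] = mask
        return logits

    def forward(
        self, X: np.ndarray, with_cache: bool = False
    ) -> tuple[np.ndarray, dict[str, np.ndarray], ForwardCache | None]:
        """Full pass: (embeddings, logits per configured level, cache).

        Deterministic: there is no dropout or other stochastic operator, so
        training- and evaluation-mode forward passes coincide.
        """
        cache = (
            ForwardCache(
                X=X, windows={}, relu_mask={}, argmax={}, features=None,
                pre_norm=None, norms=None, embeddings=None, hidden={}, hidden_mask={},
            )
            if with_cache
            else None
        )
        feats = self.extract_features(X, cache)
        emb = self.embed(feats, cache)
        logits = {lvl: self.classify(emb, lvl, cache) for lvl in self.config.levels}
        return emb, logits, cache

    def embed_sequences(self, X: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Embeddings only, computed in batches (evaluation mode)."""
        out = []
        for i in range(0, X.shape[0], batch_size):
            feats = self.extract_features(X[i : i + batch_size])
            out.append(self.embed(feats))
        return np.concatenate(out, axis=0)

    # ----------------------------------------------------------------- backward

    def backward(
        self,
        cache: ForwardCache,
        dlogits: Mapping[str, np.ndarray],
        dembed_extra: np.ndarray | None = None,
    ) -> dict[str, np.ndarray]:
        """Backpropagate loss gradients.

        dlogits: per-level gradient of the loss w.r.t. branch logits.
        dembed_extra: additional gradient w.r.t. the (normalized) embeddings,
        e.g. from the center loss.  Returns gradients for every parameter;
        the classifier L2 penalty's contribution is included for branch weights.
        """
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        dE = np.zeros_like(cache.embeddings)
        for level, dl in dlogits.items():
            if level not in cfg.levels:
                raise ModelError(f"branch not present for level {level!r}")
            h = cache.hidden[level]
            grads[f"{level}_W2"] = h.T @ dl + 2 * cfg.classifier_l2 * self.params[f"{level}_W2"]
            grads[f"{level}_b2"] = dl.sum(axis=0)
            dh = (dl @ self.params[f"{level}_W2"].T) * cache.hidden_mask[level]
            grads[f"{level}_W1"] = (
                cache.embeddings.T @ dh + 2 * cfg.classifier_l2 * self.params[f"{level}_W1"]
            )
            grads[f"{level}_b1"] = dh.sum(axis=0)
            dE += dh @ self.params[f"{level}_W1"].T
        if dembed_extra is not None:
            dE = dE + dembed_extra
        # through L2 normalization: dz = (dE - e (e . dE)) / ||z||
        e = cache.embeddings
        dz = (dE - e * np.sum(e * dE, axis=1, keepdims=True)) / cache.norms[:, None]
        grads["embed_W"] = cache.features.T @ dz
        if cfg.embed_bias:
            grads["embed_b"] = dz.sum(axis=0)
        dfeat = dz @ self.params["embed_W"].T
        F = cfg.filters_per_kernel
        for i, k in enumerate(cfg.kernel_sizes):
            dpool = dfeat[:, i * F : (i + 1) * F]  # (B, F)
            wf = cache.windows[k]
            B, P, _ = wf.shape
            dZ = np.zeros((B, P, F))
            np.put_along_axis(dZ, cache.argmax[k][:, None, :], dpool[:, None, :], axis=1)
            dZ *= cache.relu_mask[k]
            grads[f"conv_W{k}"] = np.einsum("bpi,bpf->if", wf, dZ, optimize=True)
            grads[f"conv_b{k}"] = dZ.sum(axis=(0, 1))
        for name in self.params:
            if name not in grads:
                grads[name] = np.zeros_like(self.params[name])
        return grads

    def l2_penalty(self) -> float:
        """Classifier-branch weight penalty added to the training loss."""
        total = 0.0
        for level in self.config.levels:
            total += np.sum(self.params[f"{level}_W1"] ** 2)
            total += np.sum(self.params[f"{level}_W2"] ** 2)
        return self.config.classifier_l2 * float(total)

    # -------------------------------------------------------------- persistence

    def state_copy(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state(self, state: Mapping[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ModelError("checkpoint parameter names do not match the model")
        for k, v in state.items():
            if v.shape != self.params[k].shape:
                raise ModelError(f"shape mismatch for parameter {k!r}")
            self.params[k] = np.array(v, dtype=np.float64)

    def fingerprint(self) -> str:
        """SHA-256 over config and parameter bytes; identifies a checkpoint."""
        h = hashlib.sha256()
        h.update(json.dumps(self.config.to_dict(), sort_keys=True).encode())
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path,
            __config__=json.dumps(self.config.to_dict()),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "DeepHierNet":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig.from_dict(json.loads(str(data["__config__"])))
            model = cls(config, seed=0)
            model.load_state({k: data[k] for k in data.files if k != "__config__"})
        return model
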
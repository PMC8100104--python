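"""Embedding database construction and nearest-neighbor similarity search.

A trained model embeds the labeled reference sequences once; queries are
embedded with the same checkpoint and answered by exact Euclidean
nearest-neighbor retrieval (no approximate index — the database sizes this
targets make brute force both exact and fast).  Retrieval accuracy at a
hierarchy level is the fraction of queries whose rank-1 hit shares the
query's class at that level (top-1 label transfer); top-k majority voting
is available as an option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import DeepHierNet
from .seqio import (
    LEVELS,
    HierLabel,
    SequenceDataset,
    read_embeddings,
    write_embeddings,
)


class SearchError(ValueError):
    pass


@dataclass
class Hit:
    query_id: str
    rank: int
    hit_id: str
    distance: float
    label: HierLabel


@dataclass
class EmbeddingDatabase:
    """Reference embeddings with labels and the producing model's fingerprint."""

    ids: list[str]
    embeddings: np.ndarray  # (n, d) unit-norm rows
    labels: list[HierLabel]
    fingerprint: str

    def __post_init__(self) -> None:
        if not (len(self.ids) == self.embeddings.shape[0] == len(self.labels)):
            raise SearchError("ids, embeddings and labels must have equal length")
        norms = np.linalg.norm(self.embeddings, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-5):
            raise SearchError("database embeddings must be unit-norm")
        if not self.fingerprint:
            raise SearchError("database must record its model fingerprint")

    def __len__(self) -> int:
        return len(self.ids)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_embeddings(self.ids, self.embeddings, out_dir / "embeddings.tsv",
                         precision=17)
        with open(out_dir / "labels.tsv", "w") as fh:
            fh.write("id\tfamily\tsubfamily\tsubsubfamily\n")
            for sid, lab in zip(self.ids, self.labels):
                fh.write(f"{sid}\t{lab.family}\t{lab.subfamily}\t{lab.subsubfamily}\n")
        (out_dir / "meta.json").write_text(
            json.dumps({"fingerprint": self.fingerprint, "n": len(self.ids),
                        "dim": int(self.embeddings.shape[1])})
        )

    @classmethod
    def load(cls, out_dir: str | Path) -> "EmbeddingDatabase":
        out_dir = Path(out_dir)
        ids, mat = read_embeddings(out_dir / "embeddings.tsv")
        labels = []
        with open(out_dir / "labels.tsv") as fh:
            next(fh)
            for line in fh:
                _, fam, sub, subsub = line.rstrip("\n").split("\t")
                labels.append(HierLabel(fam, sub, subsub))
        meta = json.loads((out_dir / "meta.json").read_text())
        return cls(ids=ids, embeddings=mat, labels=labels,
                   fingerprint=meta["fingerprint"])


def build_database(
    model: DeepHierNet, dataset: SequenceDataset, max_len: int = 1000
) -> EmbeddingDatabase:
    """Embed every labeled sequence once (evaluation mode) into a database."""
    for s in dataset.sequences:
        if s.label is None:
            raise SearchError(f"sequence {s.id!r} is unlabeled")
    X = dataset.encode(max_len)
    emb = model.embed_sequences(X)
    return EmbeddingDatabase(
        ids=dataset.ids(),
        embeddings=emb,
        labels=[s.label for s in dataset.sequences],
        fingerprint=model.fingerprint(),
    )


def query(
    db: EmbeddingDatabase,
    query_embeddings: np.ndarray,
    query_ids: Sequence[str],
    k: int = 5,
) -> list[list[Hit]]:
    """Exact k-nearest-neighbor hits per query, ascending by distance.

    Ties are broken by database order (stable sort).  Returns min(k, |db|)
    hits per query.
    """
    if k < 1:
        raise SearchError("k must be >= 1")
    query_embeddings = np.atleast_2d(np.asarray(query_embeddings, dtype=float))
    if query_embeddings.shape[1] != db.embeddings.shape[1]:
        raise SearchError("query embedding dimension does not match the database")
    # ||q - x||^2 = ||q||^2 - 2 q.x + ||x||^2
    d2 = (
        np.sum(query_embeddings**2, axis=1)[:, None]
        - 2 * query_embeddings @ db.embeddings.T
        + np.sum(db.embeddings**2, axis=1)[None, :]
    )
    d = np.sqrt(np.maximum(d2, 0.0))
    kk = min(k, len(db))
    results = []
    for qi, qid in enumerate(query_ids):
        order = np.argsort(d[qi], kind="stable")[:kk]
        results.append(
            [
                Hit(query_id=qid, rank=r + 1, hit_id=db.ids[j],
                    distance=float(d[qi, j]), label=db.labels[j])
                for r, j in enumerate(order)
            ]
        )
    return results


def query_sequences(
    db: EmbeddingDatabase,
    model: DeepHierNet,
    dataset: SequenceDataset,
    k: int = 5,
    max_len: int = 1000,
) -> list[list[Hit]]:
    """Embed query sequences with the database's model and search."""
    if model.fingerprint() != db.fingerprint:
        raise SearchError(
            "model fingerprint does not match the database; re-embed with the "
            "checkpoint that built it"
        )
    X = dataset.encode(max_len)
    emb = model.embed_sequences(X)
    return query(db, emb, dataset.ids(), k=k)


def retrieval_accuracy(
    db: EmbeddingDatabase,
    model: DeepHierNet,
    queries: SequenceDataset,
    level: str,
    max_len: int = 1000,
    top_k_vote: int = 1,
) -> float:
    """Fraction of queries whose retrieved label matches at the given level.

    Default is top-1 label transfer; with top_k_vote > 1 the majority label
    among the first k hits is used (ties broken by best rank).
    """
    if len(queries) == 0:
        raise SearchError("query set is empty")
    if level not in LEVELS:
        raise SearchError(f"unknown hierarchy level {level!r}")
    hits = query_sequences(db, model, queries, k=top_k_vote, max_len=max_len)
    correct = 0
    for seq, qh in zip(queries.sequences, hits):
        if top_k_vote == 1:
            predicted = qh[0].label.at(level)
        else:
            counts: dict[str, int] = {}
            first_rank: dict[str, int] = {}
            for h in qh:
                lab = h.label.at(level)
                counts[lab] = counts.get(lab, 0) + 1
                first_rank.setdefault(lab, h.rank)
            predicted = max(counts, key=lambda lab: (counts[lab], -first_rank[lab]))
        if predicted == seq.label.at(level):
            correct += 1
    return correct / len(queries)
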
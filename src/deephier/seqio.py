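"""Sequence and label I/O, hierarchy validation, and one-hot encoding.

Protein sequences come in as FASTA; three-level class labels
(family / subfamily / sub-subfamily) come in as a TSV with a header row
``id<TAB>family<TAB>subfamily<TAB>subsubfamily``.  Sequences are encoded
for the network as fixed-length ``L x 20`` one-hot matrices over the 20
standard amino acids in alphabetical one-letter order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO as _BioSeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter order.  Column i of
#: an encoded matrix corresponds to AMINO_ACIDS[i].
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Hierarchy levels, coarsest first.
LEVELS: tuple[str, str, str] = ("family", "subfamily", "subsubfamily")


class SeqIOError(ValueError):
    """Raised for malformed sequence or label inputs."""


class HierarchyError(SeqIOError):
    """Raised when a label table violates the strict three-level tree."""


@dataclass(frozen=True)
class HierLabel:
    """A sequence's (family, subfamily, sub-subfamily) class triple."""

    family: str
    subfamily: str
    subsubfamily: str

    def at(self, level: str) -> str:
        if level not in LEVELS:
            raise KeyError(f"unknown hierarchy level {level!r}")
        return getattr(self, level)

    def astuple(self) -> tuple[str, str, str]:
        return (self.family, self.subfamily, self.subsubfamily)


@dataclass
class ProteinSequence:
    """A named amino-acid sequence with an optional hierarchical label."""

    id: str
    residues: str
    label: HierLabel | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise SeqIOError(f"sequence {self.id!r} has empty residues")

    def __len__(self) -> int:
        return len(self.residues)


class HierarchyTable:
    """The global three-level label tree.

    Enforces that every sub-subfamily has exactly one subfamily parent and
    every subfamily exactly one family parent, so the three levels form a
    strict tree with families at the root level.
    """

    def __init__(
        self,
        subsub_to_sub: dict[str, str],
        sub_to_fam: dict[str, str],
        counts: dict[str, int] | None = None,
    ) -> None:
        self.subsub_to_sub = dict(subsub_to_sub)
        self.sub_to_fam = dict(sub_to_fam)
        for sub in self.subsub_to_sub.values():
            if sub not in self.sub_to_fam:
                raise HierarchyError(f"subfamily {sub!r} has no family parent")
        self.families = sorted(set(self.sub_to_fam.values()))
        self.subfamilies = sorted(self.sub_to_fam)
        self.subsubfamilies = sorted(self.subsub_to_sub)
        #: per-sub-subfamily sequence counts (may be empty for label-only tables)
        self.counts = dict(counts or {})
        if not (len(self.families) <= len(self.subfamilies) <= len(self.subsubfamilies)):
            raise HierarchyError(
                "level sizes must satisfy |families| <= |subfamilies| <= |sub-subfamilies|"
            )

    @classmethod
    def from_labels(cls, labels: Iterable[HierLabel]) -> "HierarchyTable":
        subsub_to_sub: dict[str, str] = {}
        sub_to_fam: dict[str, str] = {}
        counts: dict[str, int] = {}
        for lab in labels:
            prev = subsub_to_sub.get(lab.subsubfamily)
            if prev is not None and prev != lab.subfamily:
                raise HierarchyError(
                    f"sub-subfamily {lab.subsubfamily!r} assigned to two subfamilies: "
                    f"{prev!r} and {lab.subfamily!r}"
                )
            subsub_to_sub[lab.subsubfamily] = lab.subfamily
            prevf = sub_to_fam.get(lab.subfamily)
            if prevf is not None and prevf != lab.family:
                raise HierarchyError(
                    f"subfamily {lab.subfamily!r} assigned to two families: "
                    f"{prevf!r} and {lab.family!r}"
                )
            sub_to_fam[lab.subfamily] = lab.family
            counts[lab.subsubfamily] = counts.get(lab.subsubfamily, 0) + 1
        return cls(subsub_to_sub, sub_to_fam, counts)

    def classes(self, level: str) -> list[str]:
        if level == "family":
            return self.families
        if level == "subfamily":
            return self.subfamilies
        if level == "subsubfamily":
            return self.subsubfamilies
        raise KeyError(f"unknown hierarchy level {level!r}")

    def n_classes(self, level: str) -> int:
        return len(self.classes(level))

    def validate_label(self, label: HierLabel) -> None:
        if label.subsubfamily not in self.subsub_to_sub:
            raise HierarchyError(f"unknown sub-subfamily {label.subsubfamily!r}")
        if self.subsub_to_sub[label.subsubfamily] != label.subfamily:
            raise HierarchyError(
                f"label triple {label.astuple()} inconsistent with hierarchy"
            )
        if self.sub_to_fam[label.subfamily] != label.family:
            raise HierarchyError(
                f"label triple {label.astuple()} inconsistent with hierarchy"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HierarchyTable):
            return NotImplemented
        return (
            self.subsub_to_sub == other.subsub_to_sub
            and self.sub_to_fam == other.sub_to_fam
        )


@dataclass
class EncodedSequence:
    """Fixed-length one-hot matrix for one sequence.

    Rows for positions past the sequence end (padding) and rows for
    non-standard residues are all-zero.
    """

    origin_id: str
    matrix: np.ndarray  # (max_len, 20) of {0,1}

    def __post_init__(self) -> None:
        rowsum = self.matrix.sum(axis=1)
        if not np.all((rowsum == 0) | (rowsum == 1)):
            raise SeqIOError("each one-hot row must sum to 0 or 1")


@dataclass
class SequenceDataset:
    """A labeled collection of sequences plus its hierarchy table."""

    sequences: list[ProteinSequence]
    hierarchy: HierarchyTable

    def __len__(self) -> int:
        return len(self.sequences)

    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def labels_at(self, level: str) -> list[str]:
        out = []
        for s in self.sequences:
            if s.label is None:
                raise SeqIOError(f"sequence {s.id!r} is unlabeled")
            out.append(s.label.at(level))
        return out

    def label_indices(self, level: str) -> np.ndarray:
        """Integer class indices at a level, under the table's sorted class order."""
        classes = {c: i for i, c in enumerate(self.hierarchy.classes(level))}
        return np.array([classes[lab] for lab in self.labels_at(level)], dtype=np.int64)

    def encode(self, max_len: int = 1000) -> np.ndarray:
        """Stack one-hot encodings into an (n, max_len, 20) float32 array."""
        return np.stack(
            [one_hot_encode(s, max_len).matrix for s in self.sequences]
        ).astype(np.float32)

    def subset(self, ids: Sequence[str]) -> "SequenceDataset":
        keep = set(ids)
        seqs = [s for s in self.sequences if s.id in keep]
        table = HierarchyTable.from_labels(
            [s.label for s in seqs if s.label is not None]
        )
        return SequenceDataset(seqs, table)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into ProteinSequence records, order preserved.

    The header token before the first whitespace becomes the id.  Duplicate
    ids and empty records are rejected.
    """
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise SeqIOError(f"FASTA record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise SeqIOError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinSequence(id=rec.id, residues=seq))
    return records


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_labels(path: str | Path, sequences: list[ProteinSequence]) -> SequenceDataset:
    """Attach hierarchical labels from a TSV table and build the hierarchy.

    The TSV must have header columns id, family, subfamily, subsubfamily.
    Every sequence must appear in the table; ids match exactly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["id", "family", "subfamily", "subsubfamily"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SeqIOError(f"label table missing columns: {missing_cols}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise SeqIOError(f"duplicate ids in label table: {dups}")
    by_id = {
        row.id: HierLabel(row.family, row.subfamily, row.subsubfamily)
        for row in df.itertuples()
    }
    missing = [s.id for s in sequences if s.id not in by_id]
    if missing:
        raise SeqIOError(f"sequences missing from label table: {missing}")
    labeled = [replace_label(s, by_id[s.id]) for s in sequences]
    table = HierarchyTable.from_labels([s.label for s in labeled])
    for s in labeled:
        table.validate_label(s.label)
    return SequenceDataset(labeled, table)


def replace_label(seq: ProteinSequence, label: HierLabel) -> ProteinSequence:
    return ProteinSequence(id=seq.id, residues=seq.residues, label=label)


def write_labels(dataset: SequenceDataset, path: str | Path) -> None:
    rows = [
        (s.id, s.label.family, s.label.subfamily, s.label.subsubfamily)
        for s in dataset.sequences
    ]
    pd.DataFrame(rows, columns=["id", "family", "subfamily", "subsubfamily"]).to_csv(
        path, sep="\t", index=False
    )


def filter_small_classes(dataset: SequenceDataset, min_count: int) -> SequenceDataset:
    """Drop every sequence whose sub-subfamily has fewer than min_count members.

    Filtering acts at sub-subfamily granularity; parents left without
    children are pruned when the hierarchy is rebuilt.  Idempotent.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    for s in dataset.sequences:
        counts[s.label.subsubfamily] = counts.get(s.label.subsubfamily, 0) + 1
    kept = [s for s in dataset.sequences if counts[s.label.subsubfamily] >= min_count]
    if not kept:
        raise SeqIOError(
            f"filtering with min_count={min_count} removed every sequence"
        )
    table = HierarchyTable.from_labels([s.label for s in kept])
    return SequenceDataset(kept, table)


def one_hot_encode(seq: ProteinSequence, max_len: int = 1000) -> EncodedSequence:
    """Encode a sequence as a (max_len, 20) one-hot matrix.

    Non-standard residues (B, J, O, U, X, Z, ...) become all-zero rows;
    sequences longer than max_len are truncated with a logged warning.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    mat = np.zeros((max_len, len(AMINO_ACIDS)), dtype=np.float32)
    residues = seq.residues
    if len(residues) > max_len:
        logger.warning(
            "sequence %s has length %d > max_len %d; truncating",
            seq.id, len(residues), max_len,
        )
        residues = residues[:max_len]
    for i, aa in enumerate(residues):
        j = AA_INDEX.get(aa)
        if j is not None:
            mat[i, j] = 1.0
    return EncodedSequence(origin_id=seq.id, matrix=mat)


def decode_one_hot(encoded: EncodedSequence) -> str:
    """Inverse of one_hot_encode for standard-alphabet sequences.

    All-zero rows terminate the sequence at the first padding row; interior
    all-zero rows (unknown residues) are rendered as 'X'.
    """
    rowsum = encoded.matrix.sum(axis=1)
    nz = np.nonzero(rowsum)[0]
    if len(nz) == 0:
        return ""
    length = nz[-1] + 1
    out = []
    for i in range(length):
        if rowsum[i] == 0:
            out.append("X")
        else:
            out.append(AMINO_ACIDS[int(np.argmax(encoded.matrix[i]))])
    return "".join(out)


def write_embeddings(
    ids: Sequence[str], embeddings: np.ndarray, path: str | Path, precision: int = 10
) -> None:
    """Write embeddings as TSV: id then d float columns, header included."""
    embeddings = np.asarray(embeddings)
    if len(ids) != embeddings.shape[0]:
        raise ValueError(
            f"{len(ids)} ids but {embeddings.shape[0]} embedding rows"
        )
    d = embeddings.shape[1] if embeddings.ndim == 2 else 0
    with open(path, "w") as fh:
        fh.write("\t".join(["id"] + [f"e{i}" for i in range(d)]) + "\n")
        for sid, row in zip(ids, embeddings):
            fh.write(sid + "\t" + "\t".join(f"{v:.{precision}e}" for v in row) + "\n")


def read_embeddings(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    ids = df["id"].tolist()
    mat = df.drop(columns=["id"]).to_numpy(dtype=np.float64)
    return ids, mat
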
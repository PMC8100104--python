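"""Embedding-space evaluation and phylogenetics.

Given unit-norm embeddings, this module computes pairwise Euclidean
distance matrices, per-level silhouette scores against the true labels,
AMI-versus-k curves from ward-linkage agglomerative clustering, UPGMA
dendrogram orderings for distance-matrix visualization, and
neighbor-joining phylogenies exported as Newick.

Silhouette here is used diagnostically: the "clustering" being scored is
the true class partition at each hierarchy level, so a positive score
means within-class embedding distances are smaller than distances to the
nearest other class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy as _sch
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_mutual_info_score, silhouette_score
from skbio import DistanceMatrix as _SkbioDM
from skbio.tree import TreeNode, nj as _skbio_nj

from .seqio import LEVELS, SequenceDataset, write_fasta


class AnalysisError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix with row/column ids."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise AnalysisError("distance matrix must be square")
        if len(self.ids) != m.shape[0]:
            raise AnalysisError("id count must match matrix size")
        if not np.allclose(m, m.T, atol=1e-9):
            raise AnalysisError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0, atol=1e-9):
            raise AnalysisError("distance matrix must have a zero diagonal")
        if np.any(m < -1e-12):
            raise AnalysisError("distances must be non-negative")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass
class AMICurve:
    """AMI score against true labels for a sweep of cluster counts k."""

    ks: list[int]
    scores: dict[str, list[float]]  # level -> AMI per k

    def argmax_k(self, level: str) -> int:
        s = self.scores[level]
        return self.ks[int(np.argmax(s))]


@dataclass
class PhyloTree:
    """Unrooted tree with leaf ids and non-negative branch lengths."""

    tree: TreeNode
    clamped_negative: bool = False  # True if NJ produced negative estimates

    def newick(self) -> str:
        return str(self.tree).strip()

    def leaf_ids(self) -> set[str]:
        return {t.name for t in self.tree.tips()}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")

    def tip_distances(self) -> DistanceMatrix:
        dm = self.tree.tip_tip_distances()
        return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float))


def pairwise_distances(
    embeddings: np.ndarray, ids: Sequence[str] | None = None
) -> DistanceMatrix:
    """Exact Euclidean distance matrix between embedding rows."""
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or embeddings.shape[0] < 2:
        raise AnalysisError("need at least 2 embeddings of common dimension")
    if ids is None:
        ids = [str(i) for i in range(embeddings.shape[0])]
    mat = squareform(pdist(embeddings, metric="euclidean"))
    return DistanceMatrix(list(ids), mat)


def silhouette_by_level(
    embeddings: np.ndarray, labels_per_level: dict[str, Sequence]
) -> dict[str, float]:
    """Mean silhouette per hierarchy level, using true labels as the partition."""
    out: dict[str, float] = {}
    for level, labels in labels_per_level.items():
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            raise AnalysisError(
                f"silhouette undefined with a single class at level {level!r}"
            )
        out[level] = float(
            silhouette_score(embeddings, labels, metric="euclidean")
        )
    return out


def agglomerative_ward(embeddings: np.ndarray, k: int) -> np.ndarray:
    """Hard partition into k clusters by ward-linkage agglomeration.

    Ward operates on the raw embedding coordinates (its variance criterion
    requires Euclidean geometry, not a precomputed distance matrix).
    """
    n = embeddings.shape[0]
    if not 1 <= k <= n:
        raise AnalysisError(f"k must be in [1, {n}], got {k}")
    if k == 1:
        return np.zeros(n, dtype=int)
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(embeddings)


def ami_curve(
    embeddings: np.ndarray,
    labels_per_level: dict[str, Sequence],
    k_from: int = 2,
    k_to: int = 100,
    step: int = 3,
) -> AMICurve:
    """AMI against each level's labels for k = k_from, k_from+step, ... <= k_to.

    AMI uses the arithmetic-mean entropy normalizer (the scikit-learn
    default).  If k_to exceeds the number of points the sweep is truncated
    with a warning.
    """
    if not labels_per_level:
        raise AnalysisError("labels_per_level must not be empty")
    n = embeddings.shape[0]
    ks = [k for k in range(k_from, k_to + 1, step)]
    if ks and ks[-1] > n:
        warnings.warn(f"truncating k sweep at n={n}")
        ks = [k for k in ks if k <= n]
    scores: dict[str, list[float]] = {lvl: [] for lvl in labels_per_level}
    for k in ks:
        clust = agglomerative_ward(embeddings, k)
        for lvl, labels in labels_per_level.items():
            scores[lvl].append(
                float(adjusted_mutual_info_score(np.asarray(labels), clust))
            )
    return AMICurve(ks=ks, scores=scores)


def neighbor_joining(dist: DistanceMatrix) -> PhyloTree:
    """Classic neighbor joining (Saitou-Nei) on an embedding distance matrix.

    Exactly recovers tree metrics from additive inputs.  Negative branch
    length estimates are clamped to zero and flagged on the returned tree.
    """
    if dist.n < 3:
        raise AnalysisError("neighbor joining needs at least 3 taxa")
    # exact symmetry and hollowness (float fuzz fails skbio's strict check)
    m = (dist.matrix + dist.matrix.T) / 2.0
    np.fill_diagonal(m, 0.0)
    dm = _SkbioDM(m, ids=dist.ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = _skbio_nj(dm, neg_as_zero=False)
    clamped = any(
        node.length is not None and node.length < 0 for node in raw.traverse()
    )
    tree = _skbio_nj(dm, neg_as_zero=True) if clamped else raw
    return PhyloTree(tree=tree, clamped_negative=clamped)


def upgma_order(dist: DistanceMatrix) -> tuple[list[str], np.ndarray]:
    """UPGMA (average-linkage) dendrogram and its leaf ordering.

    Returns the leaf ids in dendrogram order — usable to sort the columns
    of a distance-matrix heat map — and the scipy linkage matrix.
    """
    Z = _sch.linkage(dist.condensed(), method="average")
    order = _sch.leaves_list(Z)
    return [dist.ids[i] for i in order], Z


def export_clusters_fasta(
    dataset: SequenceDataset,
    cluster_labels: Sequence,
    out_dir: str | Path,
) -> list[Path]:
    """Write one FASTA per cluster (inputs for external alignment/logo tools)."""
    cluster_labels = list(cluster_labels)
    if len(cluster_labels) != len(dataset.sequences):
        raise AnalysisError("cluster labels must align with the dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups: dict[str, list] = {}
    for seq, lab in zip(dataset.sequences, cluster_labels):
        groups.setdefault(str(lab), []).append(seq)
    paths = []
    for lab in sorted(groups):
        seqs = groups[lab]
        if not seqs:
            warnings.warn(f"cluster {lab} is empty; skipped")
            continue
        p = out_dir / f"cluster_{lab}.fasta"
        write_fasta(seqs, p)
        paths.append(p)
    return paths
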
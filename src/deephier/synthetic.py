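"""Synthetic hierarchical protein families with planted, level-specific motifs.

The generator emulates the structure a hierarchical family classifier
exploits in real protein superfamilies: every node of a strict three-level
class tree (family -> subfamily -> sub-subfamily) contributes one conserved
motif to all sequences below it, over an i.i.d. background of the 20
standard residues.  A sequence therefore carries three planted motifs — one
per ancestral level — each independently corrupted by point substitutions.

Motif placement uses disjoint windows (family motif in the first third of
the sequence, subfamily in the second, sub-subfamily in the last) so
placements can never collide.  At mutation rate 0 a plain substring search
recovers the true partition at every level, which is the oracle the
training tests lean on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import AMINO_ACIDS, HierLabel, HierarchyTable, ProteinSequence, SequenceDataset


@dataclass(frozen=True)
class MotifSpec:
    """A conserved motif owned by one node of the class tree."""

    node: tuple[str, ...]  # path from root, e.g. ("F1", "F1_S0", "F1_S0_SS1")
    motif: str
    window: tuple[int, int]  # [start, stop) interval of allowed start positions


@dataclass
class FamilySpec:
    """Blueprint for a synthetic three-level family tree.

    Holds the tree shape, one distinct motif per tree node with its
    placement window, the background residue distribution, and the seed
    that produced it.
    """

    n_families: int
    n_subfam_per: int
    n_subsub_per: int
    motif_lengths: tuple[int, int, int]
    seq_length: int
    motifs: dict[tuple[str, ...], MotifSpec]
    background: np.ndarray  # (20,) residue probabilities
    seed: int

    def leaf_paths(self) -> list[tuple[str, str, str]]:
        out = []
        for f in range(self.n_families):
            fam = f"F{f}"
            for s in range(self.n_subfam_per):
                sub = f"{fam}_S{s}"
                for ss in range(self.n_subsub_per):
                    out.append((fam, sub, f"{sub}_SS{ss}"))
        return out

    def motifs_for_leaf(self, path: tuple[str, str, str]) -> list[MotifSpec]:
        fam, sub, subsub = path
        return [
            self.motifs[(fam,)],
            self.motifs[(fam, sub)],
            self.motifs[(fam, sub, subsub)],
        ]


@dataclass
class SyntheticDataset:
    """Simulated labeled sequences plus the spec that produced them."""

    dataset: SequenceDataset
    spec: FamilySpec
    n_per_class: int

    @property
    def sequences(self) -> list[ProteinSequence]:
        return self.dataset.sequences


def _sample_motif(rng: np.random.Generator, length: int, background: np.ndarray) -> str:
    idx = rng.choice(len(AMINO_ACIDS), size=length, p=background)
    return "".join(AMINO_ACIDS[i] for i in idx)


def build_spec(
    n_fam: int,
    n_subfam_per: int,
    n_subsub_per: int,
    motif_lengths: tuple[int, int, int] = (8, 6, 5),
    seq_length: int = 200,
    seed: int = 0,
    background: np.ndarray | None = None,
) -> FamilySpec:
    """Sample a FamilySpec: one distinct motif per tree node, deterministic in seed.

    Motif placement windows are the thirds of the sequence, shrunk so a
    motif started anywhere in its window fits inside it.
    """
    if min(n_fam, n_subfam_per, n_subsub_per) < 1:
        raise ValueError("tree shape counts must be >= 1")
    if min(motif_lengths) < 3:
        raise ValueError("motif lengths must be >= 3")
    if sum(motif_lengths) >= seq_length:
        raise ValueError("sequence length must exceed the summed motif lengths")
    if background is None:
        background = np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    background = np.asarray(background, dtype=float)
    if background.shape != (len(AMINO_ACIDS),) or abs(background.sum() - 1) > 1e-9:
        raise ValueError("background must be a length-20 probability vector")

    n_nodes_per_level = (
        n_fam,
        n_fam * n_subfam_per,
        n_fam * n_subfam_per * n_subsub_per,
    )
    for length, n_nodes in zip(motif_lengths, n_nodes_per_level):
        if n_nodes > len(AMINO_ACIDS) ** length:
            raise ValueError(
                f"cannot draw {n_nodes} distinct motifs of length {length}"
            )

    rng = np.random.default_rng(seed)
    third = seq_length // 3
    windows = [
        (0, third - motif_lengths[0]),
        (third, 2 * third - motif_lengths[1]),
        (2 * third, seq_length - motif_lengths[2]),
    ]
    for (lo, hi), length in zip(windows, motif_lengths):
        if hi < lo:
            raise ValueError(
                f"motif of length {length} does not fit its placement window"
            )

    motifs: dict[tuple[str, ...], MotifSpec] = {}
    used: set[str] = set()

    def draw(level: int) -> str:
        # reject not just duplicates but any substring containment between
        # motifs, so exact substring search can never confuse two tree nodes
        for _ in range(1000):
            m = _sample_motif(rng, motif_lengths[level], background)
            if all(m not in u and u not in m for u in used):
                used.add(m)
                return m
        raise ValueError("could not draw a distinct motif; alphabet exhausted")

    for f in range(n_fam):
        fam = f"F{f}"
        motifs[(fam,)] = MotifSpec((fam,), draw(0), windows[0])
        for s in range(n_subfam_per):
            sub = f"{fam}_S{s}"
            motifs[(fam, sub)] = MotifSpec((fam, sub), draw(1), windows[1])
            for ss in range(n_subsub_per):
                subsub = f"{sub}_SS{ss}"
                motifs[(fam, sub, subsub)] = MotifSpec(
                    (fam, sub, subsub), draw(2), windows[2]
                )
    return FamilySpec(
        n_families=n_fam,
        n_subfam_per=n_subfam_per,
        n_subsub_per=n_subsub_per,
        motif_lengths=tuple(motif_lengths),
        seq_length=seq_length,
        motifs=motifs,
        background=background,
        seed=seed,
    )


def _mutate(rng: np.random.Generator, motif: str, rate: float) -> str:
    if rate == 0:
        return motif
    out = list(motif)
    hits = rng.random(len(motif)) < rate
    for i in np.nonzero(hits)[0]:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_sequences(
    spec: FamilySpec,
    n_per_class: int,
    mutation_rate: float = 0.05,
    seed: int = 0,
    length_jitter: float = 0.0,
) -> SyntheticDataset:
    """Simulate n_per_class sequences for every leaf (sub-subfamily) class.

    Each sequence is background noise with its three ancestral motifs
    planted at uniformly drawn starts inside their level's window, each
    motif position then substituted independently with probability
    mutation_rate.  With length_jitter > 0 sequence lengths vary uniformly
    by up to +-jitter fraction (motif windows stay those of the nominal
    length, truncated sequences keep at least the last window).
    """
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation_rate must be in [0, 1)")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    sequences: list[ProteinSequence] = []
    for fam, sub, subsub in spec.leaf_paths():
        label = HierLabel(fam, sub, subsub)
        for j in range(n_per_class):
            L = spec.seq_length
            if length_jitter > 0:
                lo = int(round(L * (1 - length_jitter)))
                hi = int(round(L * (1 + length_jitter)))
                L = int(rng.integers(lo, hi + 1))
            own = {m.motif for m in spec.motifs_for_leaf((fam, sub, subsub))}
            foreign = [m.motif for m in spec.motifs.values() if m.motif not in own]
            # resample until no foreign node's motif occurs by chance, so an
            # exact substring search is unambiguous at mutation rate 0
            for _attempt in range(100):
                idx = rng.choice(len(AMINO_ACIDS), size=L, p=spec.background)
                seq = [AMINO_ACIDS[i] for i in idx]
                starts: list[tuple[int, str]] = []
                for mspec in spec.motifs_for_leaf((fam, sub, subsub)):
                    lo, hi = mspec.window
                    hi = min(hi, L - len(mspec.motif))
                    if hi < lo:
                        raise ValueError(
                            f"motif window {mspec.window} does not fit length-{L} sequence"
                        )
                    start = int(rng.integers(lo, hi + 1))
                    seq[start : start + len(mspec.motif)] = list(mspec.motif)
                    starts.append((start, mspec.motif))
                if not any(m in "".join(seq) for m in foreign):
                    break
            else:  # pragma: no cover - p(100 collisions) is negligible
                raise ValueError("could not place motifs without collisions")
            # mutate each planted motif's positions after placement
            for start, motif in starts:
                mutated = _mutate(rng, motif, mutation_rate)
                seq[start : start + len(mutated)] = list(mutated)
            sequences.append(
                ProteinSequence(id=f"{subsub}_{j:04d}", residues="".join(seq), label=label)
            )
    table = HierarchyTable.from_labels([s.label for s in sequences])
    return SyntheticDataset(
        dataset=SequenceDataset(sequences, table), spec=spec, n_per_class=n_per_class
    )


def recover_partition_by_substring(
    dataset: SyntheticDataset,
) -> dict[str, list[tuple[str, str, str]]]:
    """Oracle: classify each sequence by exact substring search for planted motifs.

    Returns id -> list of matching leaf paths.  At mutation rate 0 every
    sequence matches exactly its own leaf path, so the oracle recovers the
    true three-level partition.
    """
    spec = dataset.spec
    out: dict[str, list[tuple[str, str, str]]] = {}
    for s in dataset.sequences:
        hits = []
        for path in spec.leaf_paths():
            if all(m.motif in s.residues for m in spec.motifs_for_leaf(path)):
                hits.append(path)
        out[s.id] = hits
    return out
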
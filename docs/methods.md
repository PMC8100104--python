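# Methods

## The model

Input sequences are one-hot encoded over the 20 standard amino acids in
alphabetical one-letter order (`ACDEFGHIKLMNPQRSTVWY`) and zero-padded to a
fixed length (default 1000). Non-standard residues (B, J, O, U, X, Z)
become all-zero rows rather than errors; sequences longer than the fixed
length are truncated with a warning. Both conventions are ours — the
upstream preprocessing of real datasets rarely documents them.

The feature extractor is a bank of one-dimensional convolutions with
several kernel sizes (default 8, 12, 16, 20, 24, 28, 32, 36; 256 filters
each), ReLU activation, and one-max pooling: each filter contributes the
single maximum of its response over all valid positions (no edge padding),
so a filter acts as a detector for one motif of roughly its kernel's
length, wherever the motif sits. Pooled values are concatenated (2048
features at the defaults), projected linearly to d = 30 dimensions, and
L2-normalized onto the unit hypersphere; the normalization is what keeps
distances bounded and comparable. A near-zero pre-normalization vector
(norm < 1e-12) raises an error instead of silently renormalizing noise.
The embedding layer carries a bias (configurable). Three MLP branches
(15 hidden units, ReLU, L2 penalty 5e-4 on their weights) classify the
family, subfamily and sub-subfamily from the shared embedding. There is no
dropout anywhere: embeddings must be deterministic functions of the input.

The whole network, including the backward pass and the Adam optimizer, is
implemented directly on numpy. The backward pass routes gradients through
the pooling argmax positions and uses the exact Jacobian
(I − e eᵀ)/‖z‖ of the normalization. It is checked against central finite
differences (relative error < 1e-4) in the test suite.

## Loss and training

Per level i the objective combines a batch-mean softmax cross-entropy
L_Si with a center loss L_Ci = Σ_j ‖d(x_j) − μ_{y_j}‖²₂, where μ_y is the
mean embedding of class y over the whole training set. The total loss is
L = Σ ω_Si L_Si + λ_C Σ ω_Ci L_Ci, and training runs three phases whose
default weights shift mass from the family level to the sub-subfamily
level while λ_C rises 0.01 → 0.3 → 0.5:

| phase | λ_C | ω_S (fam/sub/subsub) | ω_C (fam/sub/subsub) |
|-------|-----|----------------------|----------------------|
| 1 family | 0.01 | 0.8 / 0.15 / 0.05 | 0.8 / 0.15 / 0.05 |
| 2 subfamily | 0.3 | 0.1 / 0.8 / 0.1 | 0.1 / 0.8 / 0.1 |
| 3 sub-subfamily | 0.5 | 0.1 / 0.25 / 0.65 | 0.1 / 0.15 / 0.75 |

Two scale conventions needed fixing where the published form is ambiguous:

- **Center-loss normalization.** The standalone `center_loss_level`
  reports the batch **sum** (so the two-point worked example
  {(1,0),(0,1)} vs center (0.5,0.5) evaluates to exactly 1.0). Inside the
  trainer the center terms enter the objective as per-sample **means**:
  with the sum convention the center gradient grows linearly with batch
  size and, at λ_C = 0.3–0.5, overwhelms the batch-mean cross-entropy by
  an order of magnitude — empirically the finer levels then never learn.
  The mean convention makes the phase weights batch-size-independent.
- **Center update schedule.** Centers are treated as constants within a
  step (no gradient flows into μ) and refreshed after **every** optimizer
  step from a cached table of whole-training-set embeddings in which the
  current batch's rows are replaced as they are recomputed; the cache is
  rebuilt exactly at each epoch end. Per-epoch-only recomputation
  (`center_update="epoch"`) is available but measurably worse: centers a
  whole epoch stale pin sibling classes together.

Remaining training choices, all configurable: Adam (learning rate 0.001
at full scale; the desk-scale benchmark uses 0.005), batch size 64
(benchmark 32), weight decay 5e-4 on convolution and embedding weights,
and a label-preserving augmentation that substitutes each encoded residue
with probability 0.03 per training batch — both regularizers exist because
at benchmark scale (32 training sequences per leaf class) the network
otherwise memorizes the training split. Epoch budgets default to 30/30/40;
the benchmark uses 3/3/40 — the coarse levels converge in a couple of
epochs there, and long coarse phases measurably do not help the finer ones.

**Checkpoint selection.** The returned model maximizes validation
sub-subfamily accuracy, but on a small validation split (48 sequences in
the benchmark) raw per-epoch selection is dominated by sampling noise: a
single lucky epoch can win while generalizing poorly. Selection therefore
scores each epoch by a 3-epoch moving average of validation accuracy
(ties to the later, more converged epoch), and a tail average of the last
10 epoch-end parameter states of the final phase (Polyak/SWA-style) is
offered as an additional candidate, adopted only if it validates at least
as well.

Ablations used in the evaluation: `no_center_loss` forces λ_C = 0 in every
phase (identical trajectories to setting λ_C = 0 by hand, asserted in
tests); `single_branch` keeps only the sub-subfamily classifier while
retaining center losses at all three levels.

## The synthetic benchmark

The generator emulates the one property the method relies on: class
identity expressed as conserved motifs at every level of a strict
three-level tree. Each tree node owns a distinct motif (default lengths
8/6/5 for family/subfamily/sub-subfamily) drawn from the background
distribution (uniform over the 20 residues, maximizing detectability
contrast); every sequence is i.i.d. background with its three ancestral
motifs planted at uniform positions within disjoint thirds of the
sequence, then each motif position mutated independently (substitution to
a uniformly random other residue). Motif draws reject substring
containment between any two motifs, and sequence backgrounds are resampled
if a foreign node's motif arises by chance, so at mutation rate 0 an exact
substring scan recovers the true partition — the oracle the training tests
build on. Sequence length is fixed (optional ±10% jitter to exercise
padding).

What this does **not** model: real amino-acid composition, positional
conservation gradients, indels, repeated or overlapping motifs, and
length/composition correlations with class identity. Passing benchmarks
here demonstrates that the implementation learns planted hierarchical
motif structure; it does not calibrate expected accuracy on real
superfamilies.

The canonical benchmark (module `deephier.benchmark`) is 3 families x 2
subfamilies x 2 sub-subfamilies, 40 sequences per leaf class, length 200,
mutation rate 0.05, split 0.8/0.1/0.1 stratified per subfamily, and a
scaled-down model: kernel sizes (6, 10, 14) x 64 filters with the
embedding dimension (30) and classifier width (15) of the full
configuration. One training run takes about a minute on one CPU core;
sizes were chosen so the complete suite plus ablation stays within a few
minutes. Across development seeds the held-out sub-subfamily accuracy of
the full model is 0.85–0.98 (coarser levels ~1.0); a single-branch
cross-entropy-only model reaches 0.96–1.00, so the residual gap at the
finest level is the price of encoding all three levels and their
compactness in one space — consistent with the finest level being the
hardest in full-scale applications of this architecture family.

## Evaluation and downstream analyses

- **Silhouette per level** uses the true labels as the partition, so a
  positive score means within-class embedding distances are smaller than
  distances to the nearest other class; computed with scikit-learn.
- **AMI vs k**: ward-linkage agglomerative clustering (scikit-learn, on
  raw embedding coordinates, as ward's variance criterion requires) for
  k = 2, 5, 8, … (step 3, up to 100 or the sample size), scored by
  adjusted mutual information with the arithmetic-mean entropy normalizer
  (the scikit-learn default).
- **Neighbor joining** (scikit-bio) on the pairwise Euclidean distance
  matrix; additive matrices are recovered exactly (asserted to 1e-9 on
  random 6-leaf trees); negative branch-length estimates are clamped to
  zero and flagged. **UPGMA** (scipy average linkage) provides the leaf
  ordering used to sort distance-matrix heat maps and is exact on
  ultrametric input.
- **Similarity search** is exact brute-force nearest neighbor in the
  embedding space (no approximate index; at these scales the exhaustive
  computation is both the oracle and fast enough). Retrieval accuracy is
  top-1 label transfer; top-k majority voting is an option.

Numerical conventions: query distances are computed via the expanded
quadratic form with clamping at 0; query ties break by database order
(stable sort); distance matrices are symmetrized and their diagonals
zeroed before tree construction to satisfy strict validators; silhouette
is undefined (raises) with a single class.

## Known limitations

- The trainer is CPU-bound numpy; full-scale configurations (2048
  features, thousands of sequences, length-1000 padding) train in hours,
  not minutes. The architecture is faithful but the implementation is not
  tuned for that scale.
- Center updates assume every class has at least one training member at
  every level (violations raise immediately).
- The benchmark's accuracy criterion at the finest level sits close to
  typical performance (~0.9), so individual seeds can land on either side
  of it; coarse-level results and the embedding-structure diagnostics are
  stable across seeds.
- Hierarchies must be strict trees; poly-parent annotations are rejected
  at load time rather than resolved.
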
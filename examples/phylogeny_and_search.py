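"""Phylogeny reconstruction and similarity search in the embedding space.

Trains a small model quickly, then (a) builds a neighbor-joining tree from
per-class mean embeddings and checks that siblings in the class tree are
neighbors in the phylogeny, and (b) answers nearest-neighbor queries from
an embedding database, transferring the top hit's labels.
"""

import numpy as np

import deephier as dh
from deephier import losses as L
from deephier.seqio import LEVELS

spec = dh.build_spec(2, 2, 2, motif_lengths=(8, 6, 5), seq_length=120, seed=4)
data = dh.simulate_sequences(spec, 20, mutation_rate=0.03, seed=4)
tr, va, te = dh.split_dataset(data.dataset, seed=4)

mc = dh.ModelConfig(
    n_classes={l: tr.hierarchy.n_classes(l) for l in LEVELS},
    kernel_sizes=(5, 9), filters_per_kernel=32, embed_dim=16,
    classifier_hidden=8, encoded_length=132,
)
cfg = dh.TrainRunConfig(
    model=mc, phases=L.default_phases((2, 2, 25)), learning_rate=0.005,
    batch_size=16, seed=4, max_len=132, weight_decay=5e-4,
)
model, _ = dh.train(cfg, tr, va)

# neighbor-joining tree over sub-subfamily mean embeddings
emb = model.embed_sequences(tr.encode(132))
classes = tr.hierarchy.subsubfamilies
lab = tr.label_indices("subsubfamily")
means = np.stack([emb[lab == i].mean(axis=0) for i in range(len(classes))])
dm = dh.pairwise_distances(means, ids=classes)
tree = dh.neighbor_joining(dm)
print("neighbor-joining tree over the 8 sub-subfamily mean embeddings:")
print(tree.newick())
print("(sub-subfamilies sharing a subfamily prefix should sit as cherries)\n")

# similarity search: test queries against the training database
db = dh.build_database(model, tr, max_len=132)
hits = dh.query_sequences(db, model, te, k=3, max_len=132)
print("first query,", hits[0][0].query_id, "-> top 3 hits:")
for h in hits[0]:
    print(f"  rank {h.rank}: {h.hit_id}  distance {h.distance:.3f}  "
          f"labels {h.label.astuple()}")
for lvl in LEVELS:
    acc = dh.retrieval_accuracy(db, model, te, lvl, max_len=132)
    print(f"top-1 retrieval accuracy at {lvl:<13}: {acc:.3f}")
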
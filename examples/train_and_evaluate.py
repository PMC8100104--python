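"""Train the hierarchical embedding model on the canonical benchmark.

Runs the full pipeline — simulate, split 0.8/0.1/0.1 per subfamily, train
the three-phase curriculum (~1 minute on one CPU core), then measure the
embedding space on the held-out test split:

- classification accuracy per hierarchy level (argmax of each branch),
- silhouette score of the test embeddings against the true labels
  (positive at every level = distances respect the hierarchy),
- the cluster count k at which ward-clustering AMI peaks (should sit near
  the true 3/6/12 class counts),
- top-1 retrieval accuracy of test queries against the training database.
"""

from deephier.benchmark import TRUE_COUNTS, run_benchmark
from deephier.seqio import LEVELS

result = run_benchmark(seed=0)

print(f"best checkpoint: {result.report.best_checkpoint}, "
      f"validation sub-subfamily accuracy {result.report.best_val_accuracy:.3f}\n")
print(f"{'level':<14} {'accuracy':>9} {'silhouette':>11} {'AMI peak k':>11} "
      f"{'true k':>7} {'retrieval':>10}")
for lvl in LEVELS:
    print(f"{lvl:<14} {result.test_accuracy[lvl]:>9.3f} "
          f"{result.silhouette[lvl]:>11.3f} {result.ami_argmax_k[lvl]:>11d} "
          f"{TRUE_COUNTS[lvl]:>7d} {result.retrieval[lvl]:>10.3f}")

print("\nreading: accuracy near 1 at coarse levels and >0.85 at the leaf "
      "level; positive silhouettes at all levels mean one metric space "
      "encodes the whole hierarchy; the AMI peak near the true class count "
      "shows distance-based clustering recovers the right granularity.")
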
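"""Simulate a hierarchical motif-planted protein family and inspect it.

Builds a 3-family x 2-subfamily x 2-sub-subfamily class tree, plants one
conserved motif per tree node, and simulates noisy sequences.  At zero
mutation rate an exact substring scan recovers the full three-level
partition, which is the ground truth every downstream module is tested
against.
"""

import deephier as dh
from deephier.synthetic import recover_partition_by_substring

spec = dh.build_spec(3, 2, 2, motif_lengths=(8, 6, 5), seq_length=200, seed=0)
print("tree nodes with planted motifs:")
for node, m in list(spec.motifs.items())[:5]:
    print(f"  {'/'.join(node):<20} {m.motif}  window {m.window}")
print(f"  ... ({len(spec.motifs)} nodes total)\n")

data = dh.simulate_sequences(spec, n_per_class=10, mutation_rate=0.0, seed=1)
print(f"simulated {len(data.sequences)} sequences "
      f"({data.dataset.hierarchy.n_classes('subsubfamily')} leaf classes x 10)")

hits = recover_partition_by_substring(data)
exact = sum(
    hits[s.id] == [(s.label.family, s.label.subfamily, s.label.subsubfamily)]
    for s in data.sequences
)
print(f"substring oracle recovers {exact}/{len(data.sequences)} labels exactly "
      "(all three planted motifs found, no foreign motif present)")

noisy = dh.simulate_sequences(spec, n_per_class=10, mutation_rate=0.05, seed=1)
s = noisy.sequences[0]
print(f"\nexample noisy sequence {s.id} ({s.label.astuple()}):\n{s.residues}")
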
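"""Greedy counter-based assignment of experiments to cross-validation
folds.

Whole genome-wide experiments are partitioned (a model trains on all
loci of the other folds and must impute entirely held-out experiments).
The counter walks through biosamples, so folds stay balanced to within
one experiment while each biosample's experiments spread across folds.
"""

from epitensor import SyntheticSpec, generate_compendium, greedy_fold_partition

comp = generate_compendium(SyntheticSpec(seed=11))
cells = comp.tensor.observed_cells()
folds = greedy_fold_partition(cells, k=5, seed=17)

print(f"{len(cells)} experiments into k=5 folds; sizes: "
      f"{folds.fold_sizes().tolist()}")
print(folds.coverage().to_string(index=False))
print("(train_assays / train_biosamples count the distinct labels available"
      " to a model trained without that fold — every row should cover the"
      " full axes, or some embeddings would go untrained)")
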
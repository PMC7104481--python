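"""The evaluation suite on one imputed track: six MSE variants, the
average-activity baseline, and peak-classification metrics (average
precision and the precision-recall break-even point) with
ambiguous-label filtering.
"""

import numpy as np

from epitensor import (SyntheticSpec, aggregate_to_windows, average_activity,
                       average_precision, epr, filter_ambiguous,
                       generate_compendium, labels_from_signal)
from epitensor.metrics import track_metrics

comp = generate_compendium(SyntheticSpec(seed=7))
cells = comp.tensor.observed_cells()
(b, a) = cells[0]
observed = comp.tensor.values[(b, a)]

# use the assay's average activity (excluding this biosample) as a
# simple "imputation" to score
imputed = average_activity(comp.tensor, a, exclude_biosamples={b})
masks = comp.annotation.masks(comp.grid)
metrics = track_metrics(observed, imputed, masks)
for name, value in metrics.items():
    print(f"{name:10s} {value:.4f}")
print("(mse1obs/mse1imp restrict to the top-1% observed/imputed positions:"
      " recall-like and precision-like views of peak recovery)")

# peak classification: score 200 bp windows against labels derived from
# the ground truth, dropping ambiguous flanking windows
labels = labels_from_signal(comp.truth_for(b, a))
scores = aggregate_to_windows(imputed)
s, y = filter_ambiguous(scores, labels)
print(f"AP  {average_precision(s, y):.3f}  (area-like summary of the PR curve)")
print(f"EPR {epr(s, y):.3f}  (precision of the top-P windows, P = #positives)")
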
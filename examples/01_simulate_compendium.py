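"""Draw a synthetic epigenome compendium and inspect its shape.

The generator emulates a consortium data matrix: mostly-missing
(biosample x assay) cells, arcsinh-scale non-negative tracks built from
shared peak loci plus biosample-specific peak programs, heavy-tailed
per-assay coverage.
"""

import numpy as np

from epitensor import SyntheticSpec, generate_compendium, missingness_summary

comp = generate_compendium(SyntheticSpec(seed=0))
summary = missingness_summary(comp.tensor)

print(f"grid: {comp.grid.n_bins} bins of {comp.grid.bin_size} bp, "
      f"{comp.grid.n_mid} mid blocks, {comp.grid.n_coarse} coarse blocks")
print(f"matrix: {len(comp.tensor.biosamples)} biosamples x "
      f"{len(comp.tensor.assays)} assays, {summary.observed} observed "
      f"({summary.percent_missing:.1f}% missing)")

cell = comp.tensor.observed_cells()[0]
track = comp.tensor.values[cell]
print(f"track {cell}: mean {track.mean():.2f}, max {track.max():.2f} "
      "(arcsinh scale; peaks rise above a low background)")

lab = comp.labels.labels
print(f"peak labels for the first track: {np.sum(lab == 1)} positive, "
      f"{np.sum(lab == -1)} ambiguous (peak flanks), {np.sum(lab == 0)} negative "
      "windows of 200 bp at 50 bp stride")
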
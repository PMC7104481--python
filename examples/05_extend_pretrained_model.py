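"""Add a new biosample to a pre-trained model with the three-step
protocol: freeze the network and all five factor matrices, append one
biosample row, and fit it from a single observed track.

Every pre-existing parameter — and therefore every already-released
imputation — stays bit-identical; only the new row is learned.
"""

import numpy as np

from epitensor import (ExtensionJob, Model, ModelConfig, SyntheticSpec,
                       TrackTensor, TrainConfig, add_axis_element,
                       average_activity, generate_compendium, mse_global, train)

comp = generate_compendium(SyntheticSpec(n_biosamples=8, n_assays=8,
                                         observed_fraction=0.6, seed=21))
model = Model.initialize(comp.grid, comp.tensor.biosamples,
                         comp.tensor.assays, ModelConfig.desk(), seed=22)
train(model, comp.tensor, comp.grid.training_region_bins(),
      TrainConfig(epochs=600, batch_size=64, seed=23))

# a "new" biosample: reuse one core biosample's tracks, renamed, fitting
# from its first-assay (accessibility-like) track only
donor = comp.tensor.biosamples[0]
fit_assay = comp.tensor.assays[0]
fit_track = comp.tensor.values[(donor, fit_assay)]
tracks = TrackTensor(comp.tensor.biosamples + ["new-biosample"],
                     comp.tensor.assays,
                     {("new-biosample", fit_assay): fit_track})
job = ExtensionJob(mode="add_biosample", identifier="new-biosample",
                   tracks=tracks, fit_epochs=50, fit_batch=64)
extended = add_axis_element(model, job, seed=24)

same = np.array_equal(extended.predict(donor, fit_assay),
                      model.predict(donor, fit_assay))
print(f"pre-existing predictions bit-identical after extension: {same}")

eval_assay = comp.tensor.assays[1]
obs = comp.tensor.values.get((donor, eval_assay))
if obs is not None:
    new_mse = mse_global(obs, extended.predict("new-biosample", eval_assay))
    base_mse = mse_global(obs, average_activity(comp.tensor, eval_assay, {donor}))
    print(f"held-out assay {eval_assay}: imputation MSE {new_mse:.4f} vs "
          f"average-activity {base_mse:.4f}")
    print("(the new row was fit from one track, yet the imputation for an"
          " assay it never saw is biosample-specific)")
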
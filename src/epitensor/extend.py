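"""Extending a pre-trained model to new biosamples and assays.

Three protocols:

``add_axis_element`` (the three-step protocol)
    Freeze the network and all five factor matrices; append one new
    biosample or assay factor row and fit only that row on pilot-region
    signal (10 epochs, batch 512 by default).  Every pre-existing parameter
    — and hence every pre-existing imputation — stays bit-identical.

``fine_tune``
    Resume training all parameters on the pooled original + additional
    experiments.

``freeze_extend`` (the comparator freeze protocol)
    Freeze the network and genomic factors; train the full biosample and
    assay matrices (including new rows) on the additional experiments only
    (100 epochs by default).

``retrain_from_scratch``
    Fresh initialization, trained on the pooled data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import GenomicGrid, TrackTensor
from .model import Model, new_embedding_row
from .train import TrainConfig, TrainableGroups, TrainLog, train


@dataclass
class ExtensionJob:
    """One new axis element and the observed tracks used to fit it."""

    mode: str                 # "add_biosample" | "add_assay"
    identifier: str
    tracks: TrackTensor       # fitting tracks, all referencing the new element
    fit_epochs: int = 10
    fit_batch: int = 512
    fit_region: np.ndarray | None = None  # default: the grid's training regions

    def __post_init__(self) -> None:
        if self.mode not in ("add_biosample", "add_assay"):
            raise ValueError(f"unknown extension mode {self.mode!r}")
        axis = 0 if self.mode == "add_biosample" else 1
        for cell in self.tracks.values:
            if cell[axis] != self.identifier:
                raise ValueError(
                    f"fitting track {cell} does not reference new element "
                    f"{self.identifier!r}")
        if not self.tracks.values:
            raise ValueError("extension job has no fitting tracks")


def add_axis_element(model: Model, job: ExtensionJob, seed: int = 0) -> Model:
    """Three-step extension: returns a model with exactly one new, trained
    factor row; all pre-existing parameters are bit-identical."""
    rng = np.random.default_rng(seed)
    out = model.copy()
    if job.mode == "add_biosample":
        if job.identifier in out.biosamples:
            raise ValueError(f"duplicate biosample {job.identifier!r}")
        out.biosamples.append(job.identifier)
        row = new_embedding_row(out.config.d_biosample, rng)
        out.factors.biosample = np.vstack([out.factors.biosample, row])
        flags = TrainableGroups(network=False, biosample=True, assay=False,
                                genome=False,
                                biosample_rows=(len(out.biosamples) - 1,))
    else:
        if job.identifier in out.assays:
            raise ValueError(f"duplicate assay {job.identifier!r}")
        out.assays.append(job.identifier)
        row = new_embedding_row(out.config.d_assay, rng)
        out.factors.assay = np.vstack([out.factors.assay, row])
        flags = TrainableGroups(network=False, biosample=False, assay=True,
                                genome=False, assay_rows=(len(out.assays) - 1,))

    region = job.fit_region
    if region is None:
        region = out.grid.training_region_bins()
    region = np.asarray(region, dtype=np.int64)
    if region.size == 0:
        raise ValueError("fitting region does not overlap the grid")
    if job.fit_epochs > 0:
        config = TrainConfig(epochs=job.fit_epochs, batch_size=job.fit_batch,
                             seed=seed)
        train(out, job.tracks, region, config, flags)
    return out


def _extend_axes(model: Model, tensor: TrackTensor, rng: np.random.Generator) -> Model:
    """Append (seeded) initialized rows for labels new to the model."""
    out = model.copy()
    for b in tensor.biosamples:
        if b not in out.biosamples and any(bb == b for bb, _ in tensor.values):
            out.biosamples.append(b)
            out.factors.biosample = np.vstack(
                [out.factors.biosample, new_embedding_row(out.config.d_biosample, rng)])
    for a in tensor.assays:
        if a not in out.assays and any(aa == a for _, aa in tensor.values):
            out.assays.append(a)
            out.factors.assay = np.vstack(
                [out.factors.assay, new_embedding_row(out.config.d_assay, rng)])
    return out


def retrain_from_scratch(
    original: TrackTensor,
    additional: TrackTensor,
    grid: GenomicGrid,
    model_config,
    config: TrainConfig,
    seed: int = 0,
) -> tuple[Model, TrainLog]:
    """Fresh model trained on the pooled original + additional experiments."""
    merged = original.merged_with(additional)
    model = Model.initialize(grid, merged.biosamples, merged.assays, model_config,
                             seed=seed)
    log = train(model, merged, grid.training_region_bins(), config)
    return model, log


def fine_tune(
    pretrained: Model,
    original: TrackTensor,
    additional: TrackTensor,
    config: TrainConfig,
    seed: int = 0,
) -> tuple[Model, TrainLog]:
    """Phase 2 of fine-tuning: new axis rows are initialized, then all
    parameter groups train on the pooled original + additional data."""
    rng = np.random.default_rng(seed)
    merged = original.merged_with(additional)
    model = _extend_axes(pretrained, merged, rng)
    log = TrainLog(seed=config.seed)
    if config.epochs > 0:
        log = train(model, merged, model.grid.training_region_bins(), config)
    return model, log


def freeze_extend(
    pretrained: Model,
    additional: TrackTensor,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> tuple[Model, TrainLog]:
    """Freeze the network and genomic factors; train the biosample and
    assay matrices (including freshly appended rows) on the additional
    experiments only."""
    rng = np.random.default_rng(seed)
    model = _extend_axes(pretrained, additional, rng)
    config = config or TrainConfig(epochs=100, batch_size=512)
    flags = TrainableGroups(network=False, biosample=True, assay=True, genome=False)
    log = TrainLog(seed=config.seed)
    if config.epochs > 0:
        log = train(model, additional, model.grid.training_region_bins(), config, flags)
    return model, log
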
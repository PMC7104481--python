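"""Desk-scale reference studies: seed-reproducible experiments that exercise
the whole pipeline end to end on synthetic compendia.

Each study generates its inputs, runs the method, and measures the result;
nothing is looked up.  Problem sizes (10-16 biosamples, 12-14 assays, 4000
bins, around 10^3 training epochs) are chosen so each study completes in
minutes on one CPU; docs/methods.md discusses what these miniatures do and
do not show about full-scale behavior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .extend import fine_tune, freeze_extend, retrain_from_scratch
from .grid import TrackTensor
from .metrics import average_activity, greedy_fold_partition, mse_global
from .model import Model, ModelConfig
from .simulate import (
    SyntheticSpec,
    generate_compendium,
    generate_sparse_additional,
    split_even_by_assay,
)
from .train import TrainConfig, fit_model, mse_on_cells, train


def _sub(seed: int, k: int) -> int:
    """Derive a child seed (< 2^31) from a base seed."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


# --- realizability & recovery -------------------------------------------

@dataclass
class RealizabilityResult:
    initial_train_mse: float
    final_train_mse: float
    train_mse_ratio: float          # final / initial on the noiseless fixture
    heldout_mse: float              # vs fresh noisy draws of held-out cells
    noise_variance: float
    heldout_over_noise_var: float


def realizability_study(seed: int = 0, epochs_stage1: int = 1000,
                        epochs_stage2: int = 600, batch: int = 64) -> RealizabilityResult:
    """Train the full stage-1 + stage-2 pipeline on matched-decoder data.

    Noiseless run: how far training MSE falls from initialization (the
    architecture can represent the truth exactly).  Noise-sd-0.3 run:
    held-out-cell MSE against fresh noisy observations, compared with the
    injected noise variance sigma^2 = 0.09.
    """
    noise_sd = 0.3
    results = {}
    for tag, sd in (("clean", 0.0), ("noisy", noise_sd)):
        comp = generate_compendium(SyntheticSpec(
            decoder="matched", noise_sd=sd, n_chromosomes=2,
            pilot_fraction=0.25, seed=_sub(seed, 1)))
        model = Model.initialize(comp.grid, comp.tensor.biosamples,
                                 comp.tensor.assays, ModelConfig.desk(),
                                 seed=_sub(seed, 2))
        initial = mse_on_cells(model, comp.tensor)
        fit_model(model, comp.tensor,
                  TrainConfig(epochs=epochs_stage1, batch_size=batch, seed=_sub(seed, 3)),
                  TrainConfig(epochs=epochs_stage2, batch_size=batch, seed=_sub(seed, 4)))
        final = mse_on_cells(model, comp.tensor)
        results[tag] = (comp, model, initial, final)

    comp, model, _, _ = results["noisy"]
    rng = np.random.default_rng(_sub(seed, 5))
    errs = []
    for i, b in enumerate(comp.tensor.biosamples):
        for j, a in enumerate(comp.tensor.assays):
            if (b, a) in comp.tensor.mask:
                continue
            obs = np.maximum(
                comp.truth[i, j] + rng.normal(0.0, noise_sd, size=comp.grid.n_bins), 0.0)
            errs.append(mse_global(obs, model.predict(b, a)))
    heldout = float(np.mean(errs))

    _, _, initial, final = results["clean"]
    return RealizabilityResult(
        initial_train_mse=initial,
        final_train_mse=final,
        train_mse_ratio=final / initial,
        heldout_mse=heldout,
        noise_variance=noise_sd ** 2,
        heldout_over_noise_var=heldout / noise_sd ** 2,
    )


# --- baseline ordering ---------------------------------------------------

@dataclass
class BaselineResult:
    specificity: float
    model_mse: float                 # mean over test tracks
    baseline_mse: float
    assays_beat: int                 # assays where the model wins on mseGlobal
    assays_total: int
    fraction_beat: float
    mean_improvement: float          # (baseline - model) / baseline
    noise_tolerance: float           # expected baseline excess from finite averaging


def baseline_study(seed: int = 0, specificity: float = 0.5, epochs: int = 1000,
                   batch: int = 64, k: int = 5) -> BaselineResult:
    """Five-fold cross-validated comparison of the trained model with the
    average-activity predictor, per assay.

    With biosample-specific structure (mixing weight >= 0.5) the model
    should beat the baseline for most assays; with mixing 0 the baseline is
    MSE-optimal up to its finite-sample excess ~sigma^2/m (m = training
    tracks per assay), so the model should not beat it beyond that
    tolerance.
    """
    comp = generate_compendium(SyntheticSpec(
        decoder="linear", specificity=specificity, seed=_sub(seed, 11)))
    tensor = comp.tensor
    folds = greedy_fold_partition(tensor.observed_cells(), k=k, seed=_sub(seed, 12))

    per_assay_model: dict[str, list[float]] = {}
    per_assay_base: dict[str, list[float]] = {}
    tolerances = []
    for f in range(k):
        train_tensor = tensor.subset(folds.training_cells(f))
        model = Model.initialize(comp.grid, tensor.biosamples, tensor.assays,
                                 ModelConfig.desk(), seed=_sub(seed, 13) + f)
        train(model, train_tensor, comp.grid.training_region_bins(),
              TrainConfig(epochs=epochs, batch_size=batch, seed=_sub(seed, 14) + f))
        for b, a in folds.cells_in_fold(f):
            others = [c for c in train_tensor.mask if c[1] == a and c[0] != b]
            if not others:
                continue
            obs = tensor.values[(b, a)]
            per_assay_model.setdefault(a, []).append(mse_global(obs, model.predict(b, a)))
            baseline = average_activity(train_tensor, a, exclude_biosamples={b})
            per_assay_base.setdefault(a, []).append(mse_global(obs, baseline))
            tolerances.append(comp.spec.noise_sd ** 2 / len(others))

    assays = sorted(per_assay_model)
    m_means = np.array([np.mean(per_assay_model[a]) for a in assays])
    b_means = np.array([np.mean(per_assay_base[a]) for a in assays])
    model_mse = float(np.mean([v for vs in per_assay_model.values() for v in vs]))
    base_mse = float(np.mean([v for vs in per_assay_base.values() for v in vs]))
    return BaselineResult(
        specificity=specificity,
        model_mse=model_mse,
        baseline_mse=base_mse,
        assays_beat=int(np.sum(m_means < b_means)),
        assays_total=len(assays),
        fraction_beat=float(np.mean(m_means < b_means)),
        mean_improvement=(base_mse - model_mse) / base_mse,
        noise_tolerance=float(np.mean(tolerances)) / base_mse,
    )


# --- extension protocols (retrain / fine-tune / freeze) ------------------

@dataclass
class ExtensionResult:
    mse_additional: dict[str, float]            # protocol -> MSE on additional test
    mse_additional_no_novel: dict[str, float]   # same, novel-activity assays removed
    mse_core: dict[str, float]                  # protocol -> MSE on core test fold
    freeze_gap: float                            # freeze - fine_tune, additional test
    freeze_gap_no_novel: float
    gap_shrink: float                            # 1 - gap_no_novel / gap
    core_spread: float                           # max relative deviation across protocols


def extension_study(seed: int = 0, epochs: int = 1500, batch: int = 64,
                    freeze_epochs: int = 100) -> ExtensionResult:
    """Compare retrain-from-scratch, fine-tune, and freeze protocols on a
    core + additional split whose additional set contains novel-activity
    assays (the knockdown-transcription analog).

    The core compendium is densely observed (16 biosamples x 14 assays at
    50% coverage) so that, as at full scale, the additional experiments do
    not materially change core-fold performance; fine-tuning splits the
    epoch budget evenly between the original-only and pooled phases (the
    governing principle is an equal total budget across protocols)."""
    comp = generate_compendium(SyntheticSpec(
        decoder="linear", specificity=0.5, observed_fraction=0.5,
        n_biosamples=16, n_assays=14, seed=_sub(seed, 21)))
    core = comp.tensor
    folds = greedy_fold_partition(core.observed_cells(), k=5, seed=_sub(seed, 22))
    core_test_cells = folds.cells_in_fold(4)
    original = core.subset(folds.training_cells(4))

    additional = generate_sparse_additional(comp, n_new_biosamples=10,
                                            seed=_sub(seed, 23))
    add_train, add_test = split_even_by_assay(additional.tensor, seed=_sub(seed, 24))

    grid = comp.grid
    mcfg = ModelConfig.desk()

    retrain, _ = retrain_from_scratch(
        original, add_train, grid, mcfg,
        TrainConfig(epochs=epochs, batch_size=batch, seed=_sub(seed, 25)),
        seed=_sub(seed, 26))

    pre_ft = Model.initialize(grid, original.biosamples, original.assays, mcfg,
                              seed=_sub(seed, 27))
    train(pre_ft, original, grid.training_region_bins(),
          TrainConfig(epochs=epochs // 2, batch_size=batch, seed=_sub(seed, 28)))
    finetuned, _ = fine_tune(
        pre_ft, original, add_train,
        TrainConfig(epochs=epochs - epochs // 2, batch_size=batch,
                    seed=_sub(seed, 29)),
        seed=_sub(seed, 30))

    pre_fz = Model.initialize(grid, original.biosamples, original.assays, mcfg,
                              seed=_sub(seed, 27))
    train(pre_fz, original, grid.training_region_bins(),
          TrainConfig(epochs=epochs, batch_size=batch, seed=_sub(seed, 28)))
    frozen, _ = freeze_extend(
        pre_fz, add_train,
        TrainConfig(epochs=freeze_epochs, batch_size=512, seed=_sub(seed, 31)),
        seed=_sub(seed, 32))

    models = {"retrain": retrain, "fine_tune": finetuned, "freeze": frozen}
    novel = set(additional.novel_assays)

    def mse_over(model: Model, tensor: TrackTensor, cells) -> float:
        usable = [c for c in cells
                  if c[0] in model.biosamples and c[1] in model.assays]
        return mse_on_cells(model, tensor, cells=usable)

    # restrict to cells every protocol's model can impute: both axis labels
    # must carry at least one *training* observation (a factor row with no
    # training data is an arbitrary initialization, not an imputation)
    trained = set(original.observed_cells()) | set(add_train.observed_cells())
    # a biosample is identifiable only if it was fitted on at least one
    # non-novel assay (a row constrained solely by an activity type the
    # core training never saw is not a meaningful imputation basis)
    trained_b = {b for b, a in trained if a not in novel}
    trained_a = {a for _, a in trained}
    test_cells = [c for c in add_test.observed_cells()
                  if c[0] in trained_b and c[1] in trained_a
                  and all(c[0] in m.biosamples and c[1] in m.assays
                          for m in models.values())]
    test_no_novel = [c for c in test_cells if c[1] not in novel]

    mse_add = {k: mse_over(m, add_test, test_cells) for k, m in models.items()}
    mse_add_nn = {k: mse_over(m, add_test, test_no_novel) for k, m in models.items()}
    mse_core = {k: mse_over(m, core, core_test_cells) for k, m in models.items()}

    gap = mse_add["freeze"] - mse_add["fine_tune"]
    gap_nn = mse_add_nn["freeze"] - mse_add_nn["fine_tune"]
    core_vals = np.array(list(mse_core.values()))
    return ExtensionResult(
        mse_additional=mse_add,
        mse_additional_no_novel=mse_add_nn,
        mse_core=mse_core,
        freeze_gap=gap,
        freeze_gap_no_novel=gap_nn,
        gap_shrink=1.0 - gap_nn / gap if gap > 0 else float("nan"),
        core_spread=float(core_vals.max() / core_vals.min() - 1.0),
    )
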
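"""Seed-reproducible synthetic epigenome compendia with known structure.

The generator emulates the statistical shape of a consortium compendium:
a mostly-missing (biosample x assay) matrix of arcsinh-scale, non-negative
signal tracks built from shared peak loci (assay-level architecture common
to all biosamples) plus biosample-specific peak programs whose strength is
set by a mixing weight.  Assay coverage counts are heavy-tailed, mirroring
the few heavily assayed marks versus the long tail of rare assays.

Decoder modes:

``linear``
    Signal is an explicit sum of shared and low-rank biosample-specific
    peak components.  With mixing weight 0 every biosample is identical,
    so the average-activity baseline is the MSE-optimal predictor.
``mlp``
    The same latent sum passed through a fixed softplus nonlinearity.
``matched``
    Ground truth is generated by an actual factor model of the target
    architecture (calibrated to realistic scale), so a trained model of
    the same shape can in principle reach zero error — the realizability
    fixture used by the training tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GenomicGrid, RegionAnnotation, TrackTensor
from .metrics import AMBIGUOUS, NEGATIVE, POSITIVE, PeakLabelSet, aggregate_to_windows
from .model import Model, ModelConfig
from .sigio import inverse_transform, write_track


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic compendium."""

    n_bins: int = 4000                 # total fine bins
    n_chromosomes: int = 1
    bin_size: int = 25
    n_biosamples: int = 10
    n_assays: int = 12
    n_shared_loci: int = 60            # shared peak loci across biosamples
    n_programs: int = 3                # biosample-specific latent programs
    loci_per_program: int = 25
    decoder: str = "linear"            # linear | mlp | matched
    noise_sd: float = 0.1              # Gaussian noise on the arcsinh scale
    observed_fraction: float = 0.35
    specificity: float = 0.5           # mixing weight for biosample-specific peaks
    pilot_fraction: float = 1.0        # fraction of each chromosome in training regions
    matched_config: ModelConfig | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.observed_fraction <= 1:
            raise ValueError("observed_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.decoder not in ("linear", "mlp", "matched"):
            raise ValueError(f"unknown decoder mode {self.decoder!r}")
        for name in ("n_bins", "n_chromosomes", "n_biosamples", "n_assays"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class _Latents:
    """Generative state kept so additional experiments can be drawn later."""

    bumps: np.ndarray          # (n_shared_loci, n_bins) shared peak shapes
    assay_amp: np.ndarray      # (n_assays, n_shared_loci)
    assay_base: np.ndarray     # (n_assays,)
    program_profiles: np.ndarray  # (n_programs, n_bins)
    U: np.ndarray              # (n_biosamples, n_programs), column-centered
    R: np.ndarray              # (n_assays, n_programs)
    arch_amp: np.ndarray       # (n_archetypes, n_shared_loci)
    arch_R: np.ndarray         # (n_archetypes, n_programs)


@dataclass
class SyntheticCompendium:
    spec: SyntheticSpec
    grid: GenomicGrid
    tensor: TrackTensor
    truth: np.ndarray          # (n_biosamples, n_assays, n_bins)
    annotation: RegionAnnotation
    labels: PeakLabelSet       # peak labels for the first (biosample, assay) track
    matched_model: Model | None = None
    latents: _Latents | None = None

    def truth_for(self, biosample: str, assay: str) -> np.ndarray:
        bi = self.tensor.biosamples.index(biosample)
        ai = self.tensor.assays.index(assay)
        return self.truth[bi, ai]


def _bump_profiles(rng, centers, n_bins, min_width=2, max_width=8):
    """Gaussian-shaped peak profiles, one per center, unit height."""
    pos = np.arange(n_bins)
    out = np.zeros((len(centers), n_bins))
    widths = rng.integers(min_width, max_width + 1, size=len(centers))
    for j, (c, wdt) in enumerate(zip(centers, widths)):
        out[j] = np.exp(-0.5 * ((pos - c) / wdt) ** 2)
    return out


def _build_grid(spec: SyntheticSpec) -> GenomicGrid:
    per_chrom = spec.n_bins // spec.n_chromosomes
    sizes = [per_chrom] * spec.n_chromosomes
    sizes[-1] += spec.n_bins - per_chrom * spec.n_chromosomes
    chroms = [(f"chr{i + 1}", n * spec.bin_size) for i, n in enumerate(sizes)]
    training = None
    if spec.pilot_fraction < 1.0:
        training = {
            name: [(0, max(spec.bin_size, int(length * spec.pilot_fraction)))]
            for name, length in chroms
        }
    return GenomicGrid(chromosomes=chroms, bin_size=spec.bin_size,
                       training_regions=training)


def _heavy_tailed_counts(rng, n_assays, n_biosamples, n_obs):
    """Per-assay observed-track counts with a Zipf-like tail, summing to
    n_obs, each in [2, n_biosamples]."""
    # at least 2 tracks per assay when the budget allows it (tiny compendia
    # fall back to 1 or 0)
    lo = min(2, n_biosamples, n_obs // n_assays)
    weights = 1.0 / (np.arange(n_assays) + 1.0) ** 0.8
    weights = weights[rng.permutation(n_assays)]
    counts = np.maximum(lo, np.floor(n_obs * weights / weights.sum()).astype(int))
    counts = np.minimum(counts, n_biosamples)
    # largest-remainder style repair to hit the exact total
    order = np.argsort(-weights, kind="stable")
    guard = 0
    while counts.sum() != n_obs:
        diff = n_obs - counts.sum()
        for a in (order if diff > 0 else order[::-1]):
            if counts.sum() == n_obs:
                break
            if diff > 0 and counts[a] < n_biosamples:
                counts[a] += 1
            elif diff < 0 and counts[a] > lo:
                counts[a] -= 1
        guard += 1
        if guard > 10_000:
            raise ValueError("requested observed cells cannot be allocated")
    return counts


def _draw_mask(rng, n_biosamples, n_assays, observed_fraction):
    capacity = n_biosamples * n_assays
    n_obs = int(round(observed_fraction * capacity))
    if n_obs > capacity:
        raise ValueError("requested observed cells exceed capacity")
    n_obs = max(n_obs, min(capacity, 1))
    counts = _heavy_tailed_counts(rng, n_assays, n_biosamples, n_obs)
    mask = np.zeros((n_biosamples, n_assays), dtype=bool)
    for a in range(n_assays):
        rows = rng.choice(n_biosamples, size=counts[a], replace=False)
        mask[rows, a] = True
    # repair: every biosample observed at least twice (swap within an assay)
    target = min(2, n_assays)
    for b in range(n_biosamples):
        while mask[b].sum() < target:
            donors = np.flatnonzero(mask.sum(axis=1) > target)
            moved = False
            for a in rng.permutation(n_assays):
                if mask[b, a]:
                    continue
                cands = [d for d in donors if mask[d, a] and d != b]
                if cands:
                    d = cands[int(rng.integers(len(cands)))]
                    mask[d, a] = False
                    mask[b, a] = True
                    moved = True
                    break
            if not moved:
                break
    return mask


def _draw_latents(rng, spec: SyntheticSpec, shared_centers, program_centers,
                  G: int, n_archetypes: int = 4) -> _Latents:
    """Latent structure for the linear/mlp decoders.

    Assays are drawn as perturbed mixtures of a few signal archetypes
    (promoter-mark-like, enhancer-mark-like, transcription-like, ...), the
    dominant regularity of real compendia and the reason imputation works;
    every assay also responds to the biosample-specific peak programs, so
    the mixing weight uniformly controls how much each track deviates from
    its assay's average activity.
    """
    K = min(n_archetypes, spec.n_assays)
    bumps = _bump_profiles(rng, shared_centers, G)
    # archetype amplitude patterns over the shared loci (sparse, heavy-tailed)
    arch_amp = rng.gamma(2.0, 0.9, size=(K, len(shared_centers))) * (
        rng.random((K, len(shared_centers))) < 0.6)
    # each assay: one dominant archetype plus a little of the others
    loading = 0.15 * rng.random((spec.n_assays, K))
    loading[np.arange(spec.n_assays), rng.integers(0, K, size=spec.n_assays)] = 1.0
    loading /= loading.sum(axis=1, keepdims=True)
    scale = 0.5 + rng.gamma(2.0, 0.3, size=spec.n_assays)  # assay-level signal scale
    assay_amp = scale[:, None] * (loading @ arch_amp)
    assay_base = rng.uniform(0.1, 0.4, size=spec.n_assays)

    profiles = np.zeros((spec.n_programs, G))
    for k in range(spec.n_programs):
        pb = _bump_profiles(rng, np.sort(program_centers[k]), G)
        profiles[k] = rng.gamma(2.0, 0.75, size=len(pb)) @ pb
    U = rng.normal(size=(spec.n_biosamples, spec.n_programs))
    U -= U.mean(axis=0, keepdims=True)
    # program responses inherited from the archetype, positive for every assay
    arch_R = rng.gamma(3.0, 0.35, size=(K, spec.n_programs)) + 0.2
    R = scale[:, None] * (loading @ arch_R)
    return _Latents(bumps=bumps, assay_amp=assay_amp, assay_base=assay_base,
                    program_profiles=profiles, U=U, R=R,
                    arch_amp=arch_amp, arch_R=arch_R)


def _saturate(x: np.ndarray) -> np.ndarray:
    """Soft ceiling emulating the compression of the arcsinh scale: real
    transformed tracks rarely exceed ~8, however deep the raw coverage."""
    return 6.0 * np.tanh(x / 6.0)


def _truth_from_latents(lat: _Latents, specificity: float, decoder: str) -> np.ndarray:
    shared = lat.assay_amp @ lat.bumps + lat.assay_base[:, None]  # (n_assays, n_bins)
    specific = np.einsum("bk,ak,kg->bag", lat.U, lat.R, lat.program_profiles)
    lin = shared[None, :, :] + specificity * specific
    if decoder == "mlp":
        return _saturate(1.1 * np.log1p(np.exp(1.2 * (lin - 0.25))))
    return _saturate(np.maximum(lin, 0.0))


def _calibrated_matched_model(spec: SyntheticSpec, grid, biosamples, assays, rng):
    """Draw a ground-truth model of the target architecture.

    The generator embeddings are structured the way real compendia are:
    assays cluster into a handful of signal archetypes (promoter marks,
    enhancer marks, transcription, accessibility, ...) and biosamples are
    variations around a common center, so most track variance is shared
    across biosamples and the truth tensor has low effective rank.  A
    generic i.i.d. draw would instead put most variance into
    biosample x assay interactions, a regime real epigenomes are not in.
    """
    config = spec.matched_config or ModelConfig.desk()
    seed = int(rng.integers(2 ** 31))
    model = Model.initialize(grid, biosamples, assays, config, seed=seed)
    n_arch = min(4, len(assays))
    archetypes = rng.uniform(-0.05, 0.05, size=(n_arch, config.d_assay))
    membership = rng.integers(0, n_arch, size=len(assays))
    model.factors.assay[:] = archetypes[membership] + 0.3 * rng.uniform(
        -0.05, 0.05, size=model.factors.assay.shape)
    center = rng.uniform(-0.05, 0.05, size=config.d_biosample)
    model.factors.biosample[:] = center + 0.25 * rng.uniform(
        -0.05, 0.05, size=model.factors.biosample.shape)
    raw = np.stack([
        np.stack([model.predict(b, a) for a in assays]) for b in biosamples
    ])
    mu, sd = float(raw.mean()), float(raw.std())
    scale = 0.6 / max(sd, 1e-12)
    # fold the affine calibration into the linear output head: the target
    # signal stays exactly representable by the architecture
    model.weights.w_out *= scale
    model.weights.b_out = 1.5 + (model.weights.b_out - mu) * scale
    truth = 1.5 + (raw - mu) * scale
    return model, truth


def _annotation_from_loci(rng, grid: GenomicGrid, shared_centers, program_centers,
                          bin_size: int) -> RegionAnnotation:
    promoters: dict[str, list] = {}
    gene_bodies: dict[str, list] = {}
    enhancers: dict[str, list] = {}

    def locate(center_bin):
        g = int(center_bin)
        for chrom, _ in grid.chromosomes:
            start, stop = grid.bin_range(chrom)
            if start <= g < stop:
                return chrom, (g - start) * bin_size, grid.chromosome_length(chrom)
        raise IndexError(g)

    n_prom = max(1, len(shared_centers) // 3)
    for c in shared_centers[:n_prom]:
        chrom, bp, length = locate(c)
        promoters.setdefault(chrom, []).append(
            (max(0, bp - 4 * bin_size), min(length, bp + 4 * bin_size)))
        body_len = int(rng.integers(40, 150)) * bin_size
        gene_bodies.setdefault(chrom, []).append(
            (min(length - 1, bp + 4 * bin_size), min(length, bp + 4 * bin_size + body_len)))
    for c in program_centers:
        chrom, bp, length = locate(c)
        enhancers.setdefault(chrom, []).append(
            (max(0, bp - 3 * bin_size), min(length, bp + 3 * bin_size)))
    return RegionAnnotation(promoters=promoters, gene_bodies=gene_bodies,
                            enhancers=enhancers)


def labels_from_signal(values: np.ndarray, bin_size: int = 25,
                       threshold_quantile: float = 0.98, flank_windows: int = 2,
                       window: int = 200, stride: int = 50) -> PeakLabelSet:
    """Window labels from a ground-truth track: windows above the signal
    quantile are positive, windows within the flank distance of a positive
    are ambiguous (peak-flank convention), the rest negative."""
    if not 0 < threshold_quantile < 1:
        raise ValueError("threshold_quantile must be in (0, 1)")
    agg = aggregate_to_windows(values, bin_size=bin_size, window=window, stride=stride)
    thr = np.quantile(agg, threshold_quantile)
    positive = agg > max(thr, 0.0)
    labels = np.full(len(agg), NEGATIVE, dtype=np.int64)
    if positive.any():
        pos_idx = np.flatnonzero(positive)
        near = np.zeros(len(agg), dtype=bool)
        for d in range(1, flank_windows + 1):
            near[np.clip(pos_idx - d, 0, len(agg) - 1)] = True
            near[np.clip(pos_idx + d, 0, len(agg) - 1)] = True
        labels[near & ~positive] = AMBIGUOUS
        labels[positive] = POSITIVE
    return PeakLabelSet(labels=labels, window=window, stride=stride)


def generate_compendium(spec: SyntheticSpec) -> SyntheticCompendium:
    """Draw a full synthetic compendium (deterministic under spec.seed)."""
    rng = np.random.default_rng(spec.seed)
    grid = _build_grid(spec)
    biosamples = [f"biosample{i:02d}" for i in range(spec.n_biosamples)]
    assays = [f"assay{i:02d}" for i in range(spec.n_assays)]
    G = grid.n_bins

    shared_centers = np.sort(rng.choice(G, size=min(spec.n_shared_loci, G), replace=False))
    program_centers = rng.choice(G, size=(spec.n_programs, min(spec.loci_per_program, G)))

    matched_model = None
    latents = None
    if spec.decoder == "matched":
        matched_model, truth = _calibrated_matched_model(spec, grid, biosamples, assays, rng)
    else:
        latents = _draw_latents(rng, spec, shared_centers, program_centers, G)
        truth = _truth_from_latents(latents, spec.specificity, spec.decoder)

    mask = _draw_mask(rng, spec.n_biosamples, spec.n_assays, spec.observed_fraction)
    values: dict[tuple[str, str], np.ndarray] = {}
    for b in range(spec.n_biosamples):
        for a in range(spec.n_assays):
            if mask[b, a]:
                noisy = truth[b, a] + rng.normal(0.0, spec.noise_sd, size=G)
                values[(biosamples[b], assays[a])] = np.maximum(noisy, 0.0)
    tensor = TrackTensor(biosamples=biosamples, assays=assays, values=values)

    annotation = _annotation_from_loci(rng, grid, shared_centers,
                                       program_centers.ravel(), spec.bin_size)
    labels = labels_from_signal(truth[0, 0], bin_size=spec.bin_size)
    return SyntheticCompendium(spec=spec, grid=grid, tensor=tensor, truth=truth,
                               annotation=annotation, labels=labels,
                               matched_model=matched_model, latents=latents)


@dataclass
class AdditionalSet:
    """Sparse 'additional' experiments extending a core compendium."""

    tensor: TrackTensor
    truth: dict[tuple[str, str], np.ndarray]
    new_biosamples: list[str]
    new_assays: list[str]
    novel_assays: list[str]


def generate_sparse_additional(
    core: SyntheticCompendium,
    n_new_biosamples: int = 8,
    n_new_assays: int = 4,
    novel_fraction: float = 0.5,
    seed: int = 1,
) -> AdditionalSet:
    """Draw additional experiments on new biosamples/assays.

    A ``novel_fraction`` of the new assays measure an activity type absent
    from the core compendium: their genomic profiles come from fresh,
    independent peak loci (the knockdown-transcription analog), so a model
    whose genomic factors are frozen to the core data cannot represent
    them.  The remaining new assays and all new biosamples are drawn from
    the core generative process and are realizable.
    """
    if core.latents is None:
        raise ValueError("additional experiments require a linear/mlp-mode core")
    spec = core.spec
    rng = np.random.default_rng(seed)
    lat = core.latents
    G = core.grid.n_bins

    new_biosamples = [f"newbio{i:02d}" for i in range(n_new_biosamples)]
    new_assays = [f"newassay{i:02d}" for i in range(n_new_assays)]
    n_novel = int(round(novel_fraction * n_new_assays))
    novel_assays = new_assays[:n_novel]
    if set(new_biosamples) & set(core.tensor.biosamples) or (
            set(new_assays) & set(core.tensor.assays)):
        raise ValueError("identifier collision with the core compendium")

    # new biosamples: fresh rows in the same latent programs, tempered —
    # sparse-compendium biosamples are mostly moderate variants of core
    # cell types (derivatives, treatments), not extreme outliers
    U_new = np.clip(rng.normal(0.0, 0.7, size=(n_new_biosamples, lat.U.shape[1])),
                    -1.5, 1.5)
    U_all = np.vstack([lat.U, U_new])

    # new core-like assays: fresh archetype mixtures over the existing loci
    K = lat.arch_amp.shape[0]
    loading = 0.15 * rng.random((n_new_assays, K))
    loading[np.arange(n_new_assays), rng.integers(0, K, size=n_new_assays)] = 1.0
    loading /= loading.sum(axis=1, keepdims=True)
    scale = 0.5 + rng.gamma(2.0, 0.3, size=n_new_assays)
    amp_new = scale[:, None] * (loading @ lat.arch_amp)
    base_new = rng.uniform(0.1, 0.4, size=n_new_assays)
    R_new = scale[:, None] * (loading @ lat.arch_R)

    # novel-activity assays: independent loci, unlike anything in the core;
    # their peak amplitudes are modulated per biosample (a knockdown track
    # still reflects its cell background)
    novel_profiles = np.zeros((n_new_assays, G))
    novel_mod = np.zeros((n_new_assays, lat.U.shape[1]))
    for j in range(n_novel):
        centers = np.sort(rng.choice(G, size=spec.n_shared_loci // 2, replace=False))
        pb = _bump_profiles(rng, centers, G)
        novel_profiles[j] = rng.gamma(2.0, 1.3, size=len(pb)) @ pb
        novel_mod[j] = rng.normal(0.0, 0.3, size=lat.U.shape[1])

    all_biosamples = list(core.tensor.biosamples) + new_biosamples
    all_assays = list(core.tensor.assays) + new_assays

    def truth_cell(bi: int, aj: int) -> np.ndarray:
        """bi indexes all_biosamples; aj indexes new assays (aj) or core assays."""
        if aj >= len(core.tensor.assays):  # a new assay
            j = aj - len(core.tensor.assays)
            if j < n_novel:
                gain = np.maximum(1.0 + spec.specificity * (U_all[bi] @ novel_mod[j]), 0.3)
                lin = 0.2 + gain * novel_profiles[j]
            else:
                shared = amp_new[j] @ lat.bumps + base_new[j]
                specific = (U_all[bi] * R_new[j]) @ lat.program_profiles
                lin = shared + spec.specificity * specific
        else:  # a core assay in a new biosample
            shared = lat.assay_amp[aj] @ lat.bumps + lat.assay_base[aj]
            specific = (U_all[bi] * lat.R[aj]) @ lat.program_profiles
            lin = shared + spec.specificity * specific
        if spec.decoder == "mlp":
            return _saturate(1.1 * np.log1p(np.exp(1.2 * (lin - 0.25))))
        return _saturate(np.maximum(lin, 0.0))

    # Additional experiments live almost entirely on the new biosamples,
    # mirroring sparse compendium additions (knockdown derivatives and
    # newly assayed cell types): core rows are touched only through core
    # assays re-measured in new biosamples.
    cells: set[tuple[int, int]] = set()
    # each new biosample: the accessibility-like first core assay plus a few more
    for i in range(n_new_biosamples):
        bi = len(core.tensor.biosamples) + i
        cells.add((bi, 0))
        extra = rng.choice(np.arange(1, len(core.tensor.assays)),
                           size=int(rng.integers(4, 7)), replace=False)
        cells.update((bi, int(a)) for a in extra)
    # each new assay: observed in several of the new biosamples
    for j in range(n_new_assays):
        aj = len(core.tensor.assays) + j
        size = min(n_new_biosamples, int(rng.integers(5, 8)))
        rows = len(core.tensor.biosamples) + rng.choice(
            n_new_biosamples, size=size, replace=False)
        cells.update((int(b), aj) for b in rows)

    truth: dict[tuple[str, str], np.ndarray] = {}
    values: dict[tuple[str, str], np.ndarray] = {}
    for bi, aj in sorted(cells):
        key = (all_biosamples[bi], all_assays[aj])
        t = truth_cell(bi, aj)
        truth[key] = t
        values[key] = np.maximum(t + rng.normal(0.0, spec.noise_sd, size=G), 0.0)
    tensor = TrackTensor(biosamples=all_biosamples, assays=all_assays, values=values)
    return AdditionalSet(tensor=tensor, truth=truth, new_biosamples=new_biosamples,
                         new_assays=new_assays, novel_assays=novel_assays)


def split_even_by_assay(tensor: TrackTensor, seed: int = 0) -> tuple[TrackTensor, TrackTensor]:
    """For each assay, evenly partition its observed biosamples into a
    training half and a test half (seeded)."""
    rng = np.random.default_rng(seed)
    train_cells: list[tuple[str, str]] = []
    test_cells: list[tuple[str, str]] = []
    by_assay: dict[str, list[str]] = {}
    for b, a in tensor.observed_cells():
        by_assay.setdefault(a, []).append(b)
    for a in sorted(by_assay):
        bs = by_assay[a]
        order = rng.permutation(len(bs))
        half = (len(bs) + 1) // 2
        for i, o in enumerate(order):
            (train_cells if i < half else test_cells).append((bs[o], a))
    return tensor.subset(train_cells), tensor.subset(test_cells)


# --- fixture export ------------------------------------------------------

def write_fixtures(comp: SyntheticCompendium, outdir) -> None:
    """Write a compendium as on-disk fixtures: raw-scale bedGraph tracks,
    a manifest TSV, grid files, BED annotations, and window labels."""
    outdir = Path(outdir)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    rows = []
    for (b, a), v in sorted(comp.tensor.values.items()):
        path = outdir / "tracks" / f"{b}_{a}.bedgraph"
        write_track(inverse_transform(v), comp.grid, path)
        rows.append({"biosample": b, "assay": a, "replicate": "pooled",
                     "path": str(path.relative_to(outdir))})
    pd.DataFrame(rows).to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    comp.grid.save(outdir / "chrom.sizes", outdir / "grid.json",
                   outdir / "pilot.bed" if comp.grid.training_regions else None)
    for name in ("promoters", "gene_bodies", "enhancers"):
        with open(outdir / f"{name}.bed", "w") as fh:
            for chrom, ivals in getattr(comp.annotation, name).items():
                for s, e in ivals:
                    fh.write(f"{chrom}\t{s}\t{e}\n")
    code = {POSITIVE: "B", NEGATIVE: "U", AMBIGUOUS: "A"}
    with open(outdir / "labels.tsv", "w") as fh:
        fh.write("window_start\tlabel\n")
        for i, lab in enumerate(comp.labels.labels):
            fh.write(f"{i * comp.labels.stride}\t{code[int(lab)]}\n")
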
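"""Genomic coordinate system, multi-resolution indexing, and the signal tensor.

The model places latent factors at three genomic resolutions: one row per
fine bin (25 bp by default), one per mid block (10 fine bins, 250 bp), and
one per coarse block (200 fine bins, 5 kbp).  Blocks are aligned to
chromosome starts and never span chromosomes; a partial trailing block at a
chromosome end gets its own index.

All coordinates are 0-based, half-open (the bedGraph/BED convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

Interval = tuple[int, int]


def _check_intervals(intervals: Sequence[Interval], length: int, chrom: str) -> None:
    prev_end = 0
    for start, end in intervals:
        if start >= end:
            raise ValueError(f"malformed interval ({start}, {end}) on {chrom}")
        if start < prev_end:
            raise ValueError(f"overlapping/unsorted intervals on {chrom} at {start}")
        if end > length:
            raise ValueError(f"interval ({start}, {end}) exceeds {chrom} length {length}")
        prev_end = end


@dataclass
class GenomicGrid:
    """A binned genome with fine/mid/coarse block structure.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Base pairs per fine bin (default 25).
    ratio_mid
        Fine bins per mid-resolution block (default 10, i.e. 250 bp).
    ratio_coarse
        Fine bins per coarse-resolution block (default 200, i.e. 5 kbp).
        Must be a multiple of ``ratio_mid``.
    training_regions
        Half-open bp intervals per chromosome used for joint (stage-1)
        training — the analog of the ENCODE pilot regions.  ``None`` means
        the whole genome.
    """

    chromosomes: list[tuple[str, int]]
    bin_size: int = 25
    ratio_mid: int = 10
    ratio_coarse: int = 200
    training_regions: dict[str, list[Interval]] | None = None

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.ratio_mid <= 0 or self.ratio_coarse <= 0:
            raise ValueError("block ratios must be positive")
        if self.ratio_coarse % self.ratio_mid != 0:
            raise ValueError("ratio_coarse must be a multiple of ratio_mid")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        lengths = dict(self.chromosomes)
        if self.training_regions is not None:
            for chrom, ivals in self.training_regions.items():
                if chrom not in lengths:
                    raise ValueError(f"training region chromosome {chrom} not in grid")
                _check_intervals(sorted(ivals), lengths[chrom], chrom)
        self._build_index()

    def _build_index(self) -> None:
        self._n_fine = np.array(
            [-(-length // self.bin_size) for _, length in self.chromosomes], dtype=np.int64
        )
        self._n_mid = -(-self._n_fine // self.ratio_mid)
        self._n_coarse = -(-self._n_fine // self.ratio_coarse)
        self._fine_offset = np.concatenate([[0], np.cumsum(self._n_fine)])
        self._mid_offset = np.concatenate([[0], np.cumsum(self._n_mid)])
        self._coarse_offset = np.concatenate([[0], np.cumsum(self._n_coarse)])
        # dense fine -> mid/coarse lookup, used for batched embedding
        mid_of = np.empty(self.n_bins, dtype=np.int64)
        coarse_of = np.empty(self.n_bins, dtype=np.int64)
        for c in range(len(self.chromosomes)):
            local = np.arange(self._n_fine[c])
            sl = slice(self._fine_offset[c], self._fine_offset[c + 1])
            mid_of[sl] = self._mid_offset[c] + local // self.ratio_mid
            coarse_of[sl] = self._coarse_offset[c] + local // self.ratio_coarse
        self._mid_of = mid_of
        self._coarse_of = coarse_of

    # --- sizes -----------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self._fine_offset[-1])

    @property
    def n_mid(self) -> int:
        return int(self._mid_offset[-1])

    @property
    def n_coarse(self) -> int:
        return int(self._coarse_offset[-1])

    @property
    def chromosome_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def chromosome_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def _chrom_index(self, chrom: str) -> int:
        try:
            return self.chromosome_names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def bin_range(self, chrom: str) -> tuple[int, int]:
        """Global [start, stop) fine-bin indices of a chromosome."""
        c = self._chrom_index(chrom)
        return int(self._fine_offset[c]), int(self._fine_offset[c + 1])

    def bins_for_chromosome(self, chrom: str) -> np.ndarray:
        start, stop = self.bin_range(chrom)
        return np.arange(start, stop, dtype=np.int64)

    def n_bins_chrom(self, chrom: str) -> int:
        start, stop = self.bin_range(chrom)
        return stop - start

    # --- multi-scale indexing -------------------------------------------
    def multiscale_indices(self, bins):
        """Map global fine-bin index/indices to (fine, mid, coarse) indices.

        Mid and coarse indices are global (offset per chromosome); within a
        chromosome they are ``floor(local_fine / ratio)``.
        """
        b = np.asarray(bins)
        if np.any(b < 0) or np.any(b >= self.n_bins):
            raise IndexError("bin index out of range")
        if np.isscalar(bins) or b.ndim == 0:
            i = int(b)
            return i, int(self._mid_of[i]), int(self._coarse_of[i])
        return b, self._mid_of[b], self._coarse_of[b]

    # --- interval helpers ------------------------------------------------
    def intervals_to_bin_mask(
        self, intervals: Mapping[str, Sequence[Interval]]
    ) -> np.ndarray:
        """Sorted global fine-bin indices overlapping any interval by >=1 bp."""
        bins: list[np.ndarray] = []
        for chrom, ivals in intervals.items():
            c = self._chrom_index(chrom)
            length = self.chromosomes[c][1]
            off = self._fine_offset[c]
            for start, end in ivals:
                if start >= end:
                    raise ValueError(f"malformed interval ({start}, {end})")
                if start < 0 or end > length:
                    raise ValueError(f"interval ({start}, {end}) outside {chrom}")
                first = start // self.bin_size
                last = -(-end // self.bin_size)  # ceil
                bins.append(np.arange(off + first, off + last, dtype=np.int64))
        if not bins:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(bins))

    def training_region_bins(self) -> np.ndarray:
        """Global fine bins covered by the training (pilot) regions."""
        if self.training_regions is None:
            return np.arange(self.n_bins, dtype=np.int64)
        return self.intervals_to_bin_mask(self.training_regions)

    # --- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "chromosomes": [[n, int(l)] for n, l in self.chromosomes],
            "bin_size": self.bin_size,
            "ratio_mid": self.ratio_mid,
            "ratio_coarse": self.ratio_coarse,
            "training_regions": None
            if self.training_regions is None
            else {c: [[int(s), int(e)] for s, e in iv] for c, iv in self.training_regions.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomicGrid":
        tr = d.get("training_regions")
        return cls(
            chromosomes=[(n, int(l)) for n, l in d["chromosomes"]],
            bin_size=int(d["bin_size"]),
            ratio_mid=int(d["ratio_mid"]),
            ratio_coarse=int(d["ratio_coarse"]),
            training_regions=None
            if tr is None
            else {c: [(int(s), int(e)) for s, e in iv] for c, iv in tr.items()},
        )

    def save(self, sizes_path, config_path, regions_path=None) -> None:
        """Write chrom-sizes TSV + JSON config (+ BED3 training regions)."""
        with open(sizes_path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")
        cfg = self.to_dict()
        cfg.pop("chromosomes")
        if regions_path is not None and self.training_regions is not None:
            with open(regions_path, "w") as fh:
                for chrom, ivals in self.training_regions.items():
                    for start, end in ivals:
                        fh.write(f"{chrom}\t{start}\t{end}\n")
            cfg["training_regions"] = str(regions_path)
        with open(config_path, "w") as fh:
            json.dump(cfg, fh, indent=2)

    @classmethod
    def load(cls, sizes_path, config_path=None) -> "GenomicGrid":
        chroms: list[tuple[str, int]] = []
        with open(sizes_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, length = line.split()[:2]
                chroms.append((name, int(length)))
        kwargs: dict = {}
        if config_path is not None:
            with open(config_path) as fh:
                cfg = json.load(fh)
            tr = cfg.get("training_regions")
            if isinstance(tr, str):
                regions: dict[str, list[Interval]] = {}
                with open(tr) as fh:
                    for line in fh:
                        if not line.strip():
                            continue
                        chrom, s, e = line.split()[:3]
                        regions.setdefault(chrom, []).append((int(s), int(e)))
                tr = regions
            kwargs = {
                "bin_size": cfg["bin_size"],
                "ratio_mid": cfg["ratio_mid"],
                "ratio_coarse": cfg["ratio_coarse"],
                "training_regions": tr,
            }
        return cls(chromosomes=chroms, **kwargs)


class MissingnessSummary(NamedTuple):
    capacity: int
    observed: int
    percent_missing: float


@dataclass
class TrackTensor:
    """Observed signal over (biosample, assay, genomic bin) with a mask.

    ``values`` maps each observed ``(biosample, assay)`` cell to its full
    per-bin vector of arcsinh-transformed signal; the observed mask is
    exactly the key set.
    """

    biosamples: list[str]
    assays: list[str]
    values: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.biosamples)) != len(self.biosamples):
            raise ValueError("duplicate biosample identifiers")
        if len(set(self.assays)) != len(self.assays):
            raise ValueError("duplicate assay identifiers")
        bset, aset = set(self.biosamples), set(self.assays)
        lengths = {len(v) for v in self.values.values()}
        if len(lengths) > 1:
            raise ValueError("track vectors have inconsistent lengths")
        for (b, a), v in self.values.items():
            if b not in bset:
                raise ValueError(f"unknown biosample {b!r} in values")
            if a not in aset:
                raise ValueError(f"unknown assay {a!r} in values")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite signal in track ({b}, {a})")

    @property
    def mask(self) -> set[tuple[str, str]]:
        return set(self.values)

    @property
    def n_bins(self) -> int:
        for v in self.values.values():
            return len(v)
        return 0

    def observed_cells(self) -> list[tuple[str, str]]:
        """Observed (biosample, assay) cells in a stable, sorted order."""
        return sorted(self.values)

    def subset(self, cells: Iterable[tuple[str, str]]) -> "TrackTensor":
        cells = set(cells)
        missing = cells - self.mask
        if missing:
            raise KeyError(f"cells not observed: {sorted(missing)[:3]}")
        return TrackTensor(
            biosamples=list(self.biosamples),
            assays=list(self.assays),
            values={c: self.values[c] for c in cells},
        )

    def merged_with(self, other: "TrackTensor") -> "TrackTensor":
        """Union of two tensors (axes and cells); conflicting cells error."""
        overlap = self.mask & other.mask
        for c in overlap:
            if not np.array_equal(self.values[c], other.values[c]):
                raise ValueError(f"conflicting data for cell {c}")
        biosamples = list(self.biosamples) + [
            b for b in other.biosamples if b not in set(self.biosamples)
        ]
        assays = list(self.assays) + [a for a in other.assays if a not in set(self.assays)]
        values = dict(self.values)
        values.update(other.values)
        return TrackTensor(biosamples=biosamples, assays=assays, values=values)


def missingness_summary(tensor: TrackTensor) -> MissingnessSummary:
    """Capacity, observed count, and percent missing of the data matrix."""
    if not tensor.biosamples or not tensor.assays:
        raise ValueError("tensor has an empty axis")
    capacity = len(tensor.biosamples) * len(tensor.assays)
    observed = len(tensor.values)
    return MissingnessSummary(capacity, observed, 100.0 * (1.0 - observed / capacity))


def matrix_missingness(n_biosamples: int, n_assays: int, observed: int) -> MissingnessSummary:
    """Missingness arithmetic from axis sizes alone (no tracks needed)."""
    if n_biosamples <= 0 or n_assays <= 0:
        raise ValueError("axis sizes must be positive")
    capacity = n_biosamples * n_assays
    if not 0 <= observed <= capacity:
        raise ValueError("observed count outside [0, capacity]")
    return MissingnessSummary(capacity, observed, 100.0 * (1.0 - observed / capacity))


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent half-open intervals."""
    out: list[Interval] = []
    for start, end in sorted(intervals):
        if start >= end:
            raise ValueError(f"malformed interval ({start}, {end})")
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


@dataclass
class RegionAnnotation:
    """Promoter / gene-body / enhancer intervals, per chromosome, merged."""

    promoters: dict[str, list[Interval]] = field(default_factory=dict)
    gene_bodies: dict[str, list[Interval]] = field(default_factory=dict)
    enhancers: dict[str, list[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("promoters", "gene_bodies", "enhancers"):
            regions = getattr(self, name)
            setattr(self, name, {c: merge_intervals(iv) for c, iv in regions.items()})

    def masks(self, grid: GenomicGrid) -> dict[str, np.ndarray]:
        return {
            "promoters": grid.intervals_to_bin_mask(self.promoters),
            "gene_bodies": grid.intervals_to_bin_mask(self.gene_bodies),
            "enhancers": grid.intervals_to_bin_mask(self.enhancers),
        }
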
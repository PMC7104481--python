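"""Track I/O: bedGraph read/write, binning, the arcsinh transform, manifests.

Raw tracks are ENCODE-style dense signal (ChIP-seq signal p-values,
read-depth-normalized DNase, stranded RNA-seq signal).  They are binned to
the grid by base-pair-weighted averaging (uncovered bases count as signal 0)
and then variance-stabilized with arcsinh(x) = ln(x + sqrt(x^2 + 1)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid import GenomicGrid, TrackTensor

Run = tuple[int, int, float]


@dataclass
class RawTrack:
    """Sparse per-chromosome runs of (start bp, end bp, value), bedGraph-style."""

    runs: dict[str, list[Run]] = field(default_factory=dict)
    biosample: str = ""
    assay: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        for chrom, rr in self.runs.items():
            prev_end = 0
            for start, end, value in rr:
                if start >= end:
                    raise ValueError(f"malformed run ({start}, {end}) on {chrom}")
                if start < prev_end:
                    raise ValueError(f"overlapping/unsorted runs on {chrom} at {start}")
                if not np.isfinite(value):
                    raise ValueError(f"non-finite value in run on {chrom}")
                prev_end = end


def select_replicate(available: Sequence[str]) -> str:
    """Pick one replicate label: 'pooled' if present, else the second in
    submission order, else the only one."""
    if len(available) == 0:
        raise ValueError("no replicates available")
    if "pooled" in available:
        return "pooled"
    if len(available) >= 2:
        return available[1]
    return available[0]


def bin_signal(track: RawTrack, grid: GenomicGrid) -> np.ndarray:
    """Average signal in each grid bin (bp-weighted; uncovered bases = 0).

    A partial trailing bin averages only over the bases that exist on the
    chromosome.
    """
    out = np.zeros(grid.n_bins, dtype=np.float64)
    B = grid.bin_size
    lengths = dict(grid.chromosomes)
    for chrom, runs in track.runs.items():
        if chrom not in lengths:
            raise ValueError(f"track chromosome {chrom!r} not in grid")
        length = lengths[chrom]
        off, stop = grid.bin_range(chrom)
        acc = np.zeros(stop - off, dtype=np.float64)
        for start, end, value in runs:
            if end > length:
                raise ValueError(f"run ({start}, {end}) exceeds {chrom} length {length}")
            first, last = start // B, (end - 1) // B
            if first == last:
                acc[first] += value * (end - start)
            else:
                acc[first] += value * ((first + 1) * B - start)
                acc[first + 1 : last] += value * B
                acc[last] += value * (end - last * B)
        # bin widths: B except possibly the trailing partial bin
        widths = np.full(stop - off, B, dtype=np.float64)
        if length % B:
            widths[-1] = length % B
        out[off:stop] = acc / widths
    return out


def arcsinh_transform(x):
    """Variance-stabilizing transform ln(x + sqrt(x^2 + 1)), elementwise."""
    arr = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input to arcsinh_transform")
    out = np.arcsinh(arr)
    return float(out) if np.isscalar(x) else out


def inverse_transform(y):
    """sinh(y): maps arcsinh-scale values back to the original signal scale."""
    arr = np.asarray(y, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input to inverse_transform")
    out = np.sinh(arr)
    return float(out) if np.isscalar(y) else out


def write_track(values: np.ndarray, grid: GenomicGrid, path) -> None:
    """Write a per-bin vector as bedGraph, run-length merging equal bins."""
    values = np.asarray(values, dtype=np.float64)
    if len(values) != grid.n_bins:
        raise ValueError("vector length does not match grid")
    with open(path, "w") as fh:
        for chrom, length in grid.chromosomes:
            off, stop = grid.bin_range(chrom)
            v = values[off:stop]
            if len(v) == 0:
                continue
            # boundaries of runs of equal value
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(v)]])
            for s, e in zip(starts, ends):
                bp_start = s * grid.bin_size
                bp_end = min(e * grid.bin_size, length)
                fh.write(f"{chrom}\t{bp_start}\t{bp_end}\t{v[s]:.17g}\n")


def read_bedgraph(path, biosample: str = "", assay: str = "", replicate: str = "") -> RawTrack:
    """Read a 4-column bedGraph (0-based, half-open) into a RawTrack."""
    runs: dict[str, list[Run]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            runs.setdefault(chrom, []).append((int(start), int(end), float(value)))
    for rr in runs.values():
        rr.sort()
    return RawTrack(runs=runs, biosample=biosample, assay=assay, replicate=replicate)


def read_bigwig(path, grid: GenomicGrid, biosample: str = "", assay: str = "",
                replicate: str = "") -> RawTrack:
    """Read a bigWig through pyBigWig behind the same RawTrack contract."""
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    runs: dict[str, list[Run]] = {}
    try:
        for chrom, _ in grid.chromosomes:
            if chrom not in bw.chroms():
                continue
            ivals = bw.intervals(chrom)
            if ivals:
                runs[chrom] = [(int(s), int(e), float(v)) for s, e, v in ivals]
    finally:
        bw.close()
    return RawTrack(runs=runs, biosample=biosample, assay=assay, replicate=replicate)


MANIFEST_COLUMNS = ["biosample", "assay", "replicate", "path"]


def read_manifest(path) -> pd.DataFrame:
    """Experiment manifest: TSV with biosample, assay, replicate, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    return df


def load_tensor(manifest: pd.DataFrame, grid: GenomicGrid, root=None) -> TrackTensor:
    """Read, replicate-select, bin, and arcsinh-transform a manifest of tracks."""
    root = Path(root) if root is not None else None
    values: dict[tuple[str, str], np.ndarray] = {}
    biosamples: list[str] = []
    assays: list[str] = []
    for (biosample, assay), group in manifest.groupby(["biosample", "assay"], sort=False):
        chosen = select_replicate(list(group["replicate"]))
        row = group[group["replicate"] == chosen].iloc[0]
        p = Path(row["path"])
        if root is not None and not p.is_absolute():
            p = root / p
        if p.suffix in (".bw", ".bigwig", ".bigWig"):
            track = read_bigwig(p, grid, biosample, assay, chosen)
        else:
            track = read_bedgraph(p, biosample, assay, chosen)
        values[(biosample, assay)] = arcsinh_transform(bin_signal(track, grid))
        if biosample not in biosamples:
            biosamples.append(biosample)
        if assay not in assays:
            assays.append(assay)
    return TrackTensor(biosamples=biosamples, assays=assays, values=values)
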
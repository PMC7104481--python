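"""Evaluation machinery: the six MSE metrics, the average-activity
baseline, paired significance testing, precision-recall metrics with
ambiguous-label masking, 200 bp window aggregation, and the greedy
cross-validation fold partitioner.

The average-activity predictor — the positionwise mean of an assay's signal
across training biosamples — is the key baseline: it makes the same
prediction for every biosample, so beating it evidences biosample-specific
imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .grid import GenomicGrid, RegionAnnotation, TrackTensor

POSITIVE, NEGATIVE, AMBIGUOUS = 1, 0, -1
_LABEL_CODES = {"B": POSITIVE, "U": NEGATIVE, "A": AMBIGUOUS}

MSE_METRICS = ("mseGlobal", "mse1obs", "mse1imp", "mseProm", "mseGene", "mseEnh")


# --- MSE family ---------------------------------------------------------

def mse_global(observed: np.ndarray, imputed: np.ndarray) -> float:
    observed = np.asarray(observed, dtype=np.float64)
    imputed = np.asarray(imputed, dtype=np.float64)
    if observed.shape != imputed.shape:
        raise ValueError("observed and imputed lengths differ")
    d = observed - imputed
    return float(d @ d) / len(d)


def top_fraction_indices(selector: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Indices of the ceil(fraction * n) largest selector values; ties are
    broken by position order (earlier positions win)."""
    n = len(selector)
    k = int(np.ceil(fraction * n))
    order = np.argsort(-np.asarray(selector, dtype=np.float64), kind="stable")
    return order[:k]


def mse_top1(observed: np.ndarray, imputed: np.ndarray, by: str = "observed",
             fraction: float = 0.01) -> float:
    """MSE restricted to the positions carrying the top 1% of observed
    (recall-like, mse1obs) or imputed (precision-like, mse1imp) signal."""
    observed = np.asarray(observed, dtype=np.float64)
    imputed = np.asarray(imputed, dtype=np.float64)
    if observed.shape != imputed.shape:
        raise ValueError("observed and imputed lengths differ")
    if len(observed) < 100:
        raise ValueError("top-1% metrics require at least 100 positions")
    if by not in ("observed", "imputed"):
        raise ValueError("by must be 'observed' or 'imputed'")
    selector = observed if by == "observed" else imputed
    idx = top_fraction_indices(selector, fraction)
    return mse_global(observed[idx], imputed[idx])


def mse_region(observed: np.ndarray, imputed: np.ndarray, mask: np.ndarray) -> float:
    """MSE restricted to a set of bins (promoters, gene bodies, enhancers)."""
    mask = np.asarray(mask, dtype=np.int64)
    if mask.size == 0:
        raise ValueError("empty region mask")
    return mse_global(np.asarray(observed)[mask], np.asarray(imputed)[mask])


def paired_t(metric_a: Sequence[float], metric_b: Sequence[float]) -> tuple[float, float]:
    """Paired t test on per-track metric differences (two-sided)."""
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if len(a) < 2:
        raise ValueError("paired t test needs n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def relative_reduction(baseline: float, value: float) -> float:
    """Fractional error reduction (baseline - value) / baseline."""
    if baseline == 0:
        raise ValueError("baseline must be nonzero")
    return (baseline - value) / baseline


# --- average-activity baseline ------------------------------------------

def average_activity(tensor: TrackTensor, assay: str,
                     exclude_biosamples: Iterable[str] = ()) -> np.ndarray:
    """Positionwise mean signal of an assay over non-excluded observed
    tracks.  The evaluated track's biosample must be excluded by the caller
    (or simply absent, as with a held-out fold)."""
    exclude = set(exclude_biosamples)
    tracks = [v for (b, a), v in sorted(tensor.values.items())
              if a == assay and b not in exclude]
    if not tracks:
        raise ValueError(f"no eligible tracks for assay {assay!r}")
    return np.mean(tracks, axis=0)


# --- window aggregation and PR metrics ----------------------------------

def aggregate_to_windows(values: np.ndarray, bin_size: int = 25,
                         window: int = 200, stride: int = 50) -> np.ndarray:
    """Mean signal in sliding windows (200 bp / 50 bp stride by default)
    over one chromosome's per-bin vector.  Windows start at 0 and are
    truncated at the chromosome end."""
    if window % bin_size or stride % bin_size:
        raise ValueError("window and stride must be multiples of the bin size")
    if window < bin_size:
        raise ValueError("window smaller than one bin")
    values = np.asarray(values, dtype=np.float64)
    wb = window // bin_size
    sb = stride // bin_size
    n = len(values)
    starts = np.arange(0, n, sb)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    ends = np.minimum(starts + wb, n)
    return (csum[ends] - csum[starts]) / (ends - starts)


@dataclass
class PeakLabelSet:
    """Window labels over 200 bp windows with a 50 bp stride:
    positive (1), negative (0), or ambiguous (-1)."""

    labels: np.ndarray
    window: int = 200
    stride: int = 50

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        bad = ~np.isin(self.labels, [POSITIVE, NEGATIVE, AMBIGUOUS])
        if np.any(bad):
            raise ValueError("labels must be in {1, 0, -1}")

    @classmethod
    def from_codes(cls, codes: Sequence[str], window: int = 200, stride: int = 50):
        """Map challenge-style codes B (bound), U (unbound), A (ambiguous)."""
        try:
            labels = np.array([_LABEL_CODES[c] for c in codes], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unknown label code {exc.args[0]!r}") from None
        return cls(labels=labels, window=window, stride=stride)

    def n_positive(self) -> int:
        return int(np.sum(self.labels == POSITIVE))


def filter_ambiguous(scores: np.ndarray, labels: PeakLabelSet) -> tuple[np.ndarray, np.ndarray]:
    """Drop ambiguous windows from scores and labels alike."""
    scores = np.asarray(scores, dtype=np.float64)
    lab = labels.labels
    if scores.shape != lab.shape:
        raise ValueError("scores and labels are not aligned")
    keep = lab != AMBIGUOUS
    if not np.any(keep):
        raise ValueError("all windows are ambiguous")
    return scores[keep], lab[keep]


def average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-wise (non-interpolated) average precision over the ranked list,
    AP = sum_k (R_k - R_{k-1}) P_k, with tied scores grouped."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("average precision needs >=1 positive and >=1 negative")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # indices where a score group ends
    group_end = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.empty(0, dtype=np.int64)
    ends = np.concatenate([group_end, [len(s) - 1]])
    tp = np.cumsum(y == 1)[ends]
    total = ends + 1
    precision = tp / total
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def epr(scores: np.ndarray, labels: np.ndarray, include_ties: bool = True) -> float:
    """Precision-recall break-even point: precision of the top-P scored
    windows where P is the number of positives.  With ``include_ties``
    (default), windows tied with the cutoff score are all included and
    precision is computed over the enlarged set."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0:
        raise ValueError("EPR needs at least one positive label")
    order = np.argsort(-scores, kind="stable")
    if include_ties:
        cutoff = scores[order[n_pos - 1]]
        sel = scores >= cutoff
        return float(np.mean(labels[sel] == 1))
    top = order[:n_pos]
    return float(np.mean(labels[top] == 1))


# --- cross-validation folds ---------------------------------------------

@dataclass
class FoldAssignment:
    """Experiment -> fold map with per-fold coverage statistics."""

    folds: dict[tuple[str, str], int]
    k: int

    def fold_sizes(self) -> np.ndarray:
        sizes = np.zeros(self.k, dtype=np.int64)
        for f in self.folds.values():
            sizes[f] += 1
        return sizes

    def cells_in_fold(self, fold: int) -> list[tuple[str, str]]:
        return sorted(c for c, f in self.folds.items() if f == fold)

    def training_cells(self, fold: int) -> list[tuple[str, str]]:
        return sorted(c for c, f in self.folds.items() if f != fold)

    def coverage(self) -> pd.DataFrame:
        """Distinct assays/biosamples in each fold's training complement."""
        rows = []
        for f in range(self.k):
            train = self.training_cells(f)
            rows.append({
                "fold": f,
                "n_test": len(self.cells_in_fold(f)),
                "train_assays": len({a for _, a in train}),
                "train_biosamples": len({b for b, _ in train}),
            })
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(b, a, f) for (b, a), f in sorted(self.folds.items())],
            columns=["biosample", "assay", "fold"],
        )


def greedy_fold_partition(experiments: Sequence[tuple[str, str]], k: int = 5,
                          seed: int = 0, shuffle: bool = True) -> FoldAssignment:
    """Assign experiments to k folds with a modular counter walked through
    biosamples: biosamples are visited in (seeded) random order, each
    biosample's experiments are shuffled, and each experiment gets
    ``fold = counter % k`` with the counter persisting across biosamples.
    This balances folds to within one experiment while spreading each
    biosample's experiments across folds."""
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    by_biosample: dict[str, list[tuple[str, str]]] = {}
    order_seen: list[str] = []
    for b, a in experiments:
        if b not in by_biosample:
            by_biosample[b] = []
            order_seen.append(b)
        by_biosample[b].append((b, a))
    biosample_order = list(order_seen)
    if shuffle:
        biosample_order = [order_seen[i] for i in rng.permutation(len(order_seen))]
    folds: dict[tuple[str, str], int] = {}
    counter = 0
    for b in biosample_order:
        exps = by_biosample[b]
        idx = rng.permutation(len(exps)) if shuffle else np.arange(len(exps))
        for i in idx:
            folds[exps[i]] = counter % k
            counter += 1
    return FoldAssignment(folds=folds, k=k)


# --- compendium-level evaluation ----------------------------------------

Imputer = Callable[[TrackTensor, str, str], np.ndarray]


def average_activity_imputer(train_tensor: TrackTensor, biosample: str,
                             assay: str) -> np.ndarray:
    return average_activity(train_tensor, assay, exclude_biosamples={biosample})


@dataclass
class MetricReport:
    """Per-track and aggregate values of the six MSE metrics."""

    per_track: pd.DataFrame
    aggregate: dict[str, float] = field(default_factory=dict)

    def by_assay(self, metric: str = "mseGlobal") -> pd.Series:
        return self.per_track.groupby("assay")[metric].mean()


def track_metrics(observed: np.ndarray, imputed: np.ndarray,
                  region_masks: dict[str, np.ndarray] | None = None) -> dict[str, float]:
    out = {
        "mseGlobal": mse_global(observed, imputed),
        "mse1obs": mse_top1(observed, imputed, by="observed"),
        "mse1imp": mse_top1(observed, imputed, by="imputed"),
    }
    if region_masks is not None:
        out["mseProm"] = mse_region(observed, imputed, region_masks["promoters"])
        out["mseGene"] = mse_region(observed, imputed, region_masks["gene_bodies"])
        out["mseEnh"] = mse_region(observed, imputed, region_masks["enhancers"])
    return out


def evaluate_compendium(
    imputer: Imputer,
    tensor: TrackTensor,
    folds: FoldAssignment,
    annotations: RegionAnnotation | None = None,
    grid: GenomicGrid | None = None,
) -> MetricReport:
    """Score every observed track against the imputer trained without its
    fold.  Tracks whose assay has no counterpart in the training complement
    are skipped with a warning."""
    masks = annotations.masks(grid) if annotations is not None and grid is not None else None
    rows = []
    for (b, a), observed in sorted(tensor.values.items()):
        fold = folds.folds[(b, a)]
        train_cells = [c for c in folds.training_cells(fold) if c in tensor.mask]
        train_tensor = tensor.subset(train_cells)
        if not any(aa == a and bb != b for bb, aa in train_cells):
            warnings.warn(f"skipping ({b}, {a}): no training-set track of assay {a!r}")
            continue
        imputed = imputer(train_tensor, b, a)
        row = {"biosample": b, "assay": a, "fold": fold}
        row.update(track_metrics(observed, imputed, masks))
        rows.append(row)
    per_track = pd.DataFrame(rows)
    aggregate = {
        m: float(per_track[m].mean()) for m in MSE_METRICS if m in per_track.columns
    }
    return MetricReport(per_track=per_track, aggregate=aggregate)


def compare_reports(method: MetricReport, baseline: MetricReport) -> pd.DataFrame:
    """Per-metric paired t test and per-assay win counts, method vs baseline."""
    keys = ["biosample", "assay"]
    merged = method.per_track.merge(baseline.per_track, on=keys, suffixes=("_m", "_b"))
    rows = []
    for m in MSE_METRICS:
        if f"{m}_m" not in merged.columns:
            continue
        t, p = paired_t(merged[f"{m}_m"], merged[f"{m}_b"])
        by_assay = merged.groupby("assay")[[f"{m}_m", f"{m}_b"]].mean()
        wins = int((by_assay[f"{m}_m"] < by_assay[f"{m}_b"]).sum())
        rows.append({
            "metric": m,
            "method_mean": float(merged[f"{m}_m"].mean()),
            "baseline_mean": float(merged[f"{m}_b"].mean()),
            "t": t, "p": p,
            "assays_won": wins, "assays_total": len(by_assay),
        })
    return pd.DataFrame(rows)
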
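"""Two-stage training: joint fitting on pilot regions, then per-chromosome
genomic factors with everything else frozen.

The loss is mean squared error on arcsinh-transformed signal, minimized
with Adam (step size 0.001, beta1 0.9, beta2 0.999, eps 1e-7).  One epoch
is one pass over the genomic axis: every bin in the training region appears
exactly once, paired with a uniformly drawn observed (biosample, assay)
cell.  Batches chunk the shuffled epoch sequence; the final short batch is
kept.

Gradients are computed by explicit backpropagation through the two-layer
ReLU decoder; embedding matrices receive sparse (row-wise) Adam updates, so
freezing contracts hold bitwise: rows that never appear in a batch are
never touched.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import GenomicGrid, TrackTensor
from .model import Model, NetworkWeights


@dataclass(frozen=True)
class TrainableGroups:
    """Which parameter groups gradient steps may modify.

    ``biosample_rows`` / ``assay_rows`` optionally restrict the trainable
    rows of those factor matrices (used when fitting a single new axis
    element to an otherwise frozen model).
    """

    network: bool = True
    biosample: bool = True
    assay: bool = True
    genome: bool = True
    biosample_rows: tuple[int, ...] | None = None
    assay_rows: tuple[int, ...] | None = None

    def any_trainable(self) -> bool:
        return self.network or self.biosample or self.assay or self.genome


def set_trainable(network=True, biosample=True, assay=True, genome=True,
                  biosample_rows=None, assay_rows=None) -> TrainableGroups:
    """Build a trainability view; training with all groups frozen errors."""
    return TrainableGroups(
        network=network, biosample=biosample, assay=assay, genome=genome,
        biosample_rows=None if biosample_rows is None else tuple(int(r) for r in biosample_rows),
        assay_rows=None if assay_rows is None else tuple(int(r) for r in assay_rows),
    )


@dataclass
class TrainConfig:
    """Optimization settings.  Full-scale defaults mirror the reference
    protocol (8000 epochs, batch 40,000, Adam defaults); desk-scale runs
    override epochs and batch_size."""

    epochs: int = 8000
    batch_size: int = 40_000
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.batch_size <= 0:
            raise ValueError("batch_size must be positive")


@dataclass
class TrainLog:
    losses: list[float] = field(default_factory=list)
    epochs: int = 0
    wall_time: float = 0.0
    seed: int = 0


class Adam:
    """Adam with dense updates for network weights and lazy row-wise
    updates for embedding matrices (untouched rows stay bit-identical)."""

    def __init__(self, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray | float] = {}
        self._v: dict[str, np.ndarray | float] = {}

    def step(self) -> None:
        self.t += 1

    def _state(self, name: str, like: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if name not in self._m:
            self._m[name] = np.zeros_like(like)
            self._v[name] = np.zeros_like(like)
        return self._m[name], self._v[name]

    def _rate(self) -> float:
        return self.lr * np.sqrt(1.0 - self.b2 ** self.t) / (1.0 - self.b1 ** self.t)

    def dense(self, name: str, param: np.ndarray, grad: np.ndarray) -> None:
        m, v = self._state(name, param)
        m *= self.b1
        m += (1 - self.b1) * grad
        v *= self.b2
        v += (1 - self.b2) * grad * grad
        param -= self._rate() * m / (np.sqrt(v) + self.eps)

    def scalar(self, name: str, value: float, grad: float) -> float:
        if name not in self._m:
            self._m[name] = 0.0
            self._v[name] = 0.0
        self._m[name] = self.b1 * self._m[name] + (1 - self.b1) * grad
        self._v[name] = self.b2 * self._v[name] + (1 - self.b2) * grad * grad
        return value - self._rate() * self._m[name] / (np.sqrt(self._v[name]) + self.eps)

    def rows(self, name: str, param: np.ndarray, rows: np.ndarray, grad: np.ndarray) -> None:
        if len(rows) == 0:
            return
        m, v = self._state(name, param)
        mr = self.b1 * m[rows] + (1 - self.b1) * grad
        vr = self.b2 * v[rows] + (1 - self.b2) * grad * grad
        m[rows], v[rows] = mr, vr
        param[rows] -= self._rate() * mr / (np.sqrt(vr) + self.eps)


def sample_epoch(tensor: TrackTensor, grid: GenomicGrid, region: np.ndarray, seed):
    """One epoch of training triples: every region bin once (shuffled),
    each paired with a uniformly drawn observed cell.

    Returns ``(biosample_idx, assay_idx, bin_idx)`` arrays; indices refer to
    the tensor's axis order.  ``seed`` may be an int or a Generator (the
    latter lets a caller thread one stream across epochs).
    """
    cells = tensor.observed_cells()
    if not cells:
        raise ValueError("tensor has no observed cells")
    region = np.asarray(region, dtype=np.int64)
    if region.size == 0:
        raise ValueError("empty training region")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bins = rng.permutation(region)
    pick = rng.integers(0, len(cells), size=len(bins))
    b_of = {b: i for i, b in enumerate(tensor.biosamples)}
    a_of = {a: i for i, a in enumerate(tensor.assays)}
    cell_b = np.array([b_of[b] for b, _ in cells], dtype=np.int64)
    cell_a = np.array([a_of[a] for _, a in cells], dtype=np.int64)
    return cell_b[pick], cell_a[pick], bins


def _forward_cache(X: np.ndarray, w: NetworkWeights):
    Z1 = X @ w.W1 + w.b1
    H1 = np.maximum(Z1, 0.0)
    Z2 = H1 @ w.W2 + w.b2
    H2 = np.maximum(Z2, 0.0)
    pred = H2 @ w.w_out + w.b_out
    return pred, (X, Z1, H1, Z2, H2)


def _backward(cache, dpred: np.ndarray, w: NetworkWeights):
    X, Z1, H1, Z2, H2 = cache
    g_wout = H2.T @ dpred
    g_bout = float(dpred.sum())
    dH2 = np.outer(dpred, w.w_out)
    dZ2 = dH2 * (Z2 > 0)
    g_W2 = H1.T @ dZ2
    g_b2 = dZ2.sum(axis=0)
    dH1 = dZ2 @ w.W2.T
    dZ1 = dH1 * (Z1 > 0)
    g_W1 = X.T @ dZ1
    g_b1 = dZ1.sum(axis=0)
    dX = dZ1 @ w.W1.T
    return (g_W1, g_b1, g_W2, g_b2, g_wout, g_bout), dX


def _scatter_rows(idx: np.ndarray, d_grad: np.ndarray, row_filter) -> tuple[np.ndarray, np.ndarray]:
    """Sum per-sample gradients into unique rows (optionally filtered)."""
    rows, inv = np.unique(idx, return_inverse=True)
    acc = np.zeros((len(rows), d_grad.shape[1]))
    np.add.at(acc, inv, d_grad)
    if row_filter is not None:
        keep = np.isin(rows, np.asarray(row_filter, dtype=np.int64))
        rows, acc = rows[keep], acc[keep]
    return rows, acc


def train(
    model: Model,
    tensor: TrackTensor,
    bins: np.ndarray,
    config: TrainConfig,
    trainable: TrainableGroups | None = None,
    optimizer: Adam | None = None,
) -> TrainLog:
    """Mini-batch MSE training of ``model`` in place on the given bins.

    Returns the per-epoch loss log.  A fresh optimizer is created unless one
    is passed in (stage boundaries re-initialize optimizer state).
    """
    trainable = trainable or TrainableGroups()
    if not trainable.any_trainable():
        raise ValueError("training requested with all parameter groups frozen")
    bins = np.asarray(bins, dtype=np.int64)
    if bins.size == 0:
        raise ValueError("empty training region")
    cells = tensor.observed_cells()
    if not cells:
        raise ValueError("tensor has no observed cells")

    cell_b = np.array([model.biosample_index(b) for b, _ in cells], dtype=np.int64)
    cell_a = np.array([model.assay_index(a) for _, a in cells], dtype=np.int64)
    Y = np.stack([np.asarray(tensor.values[c], dtype=np.float64) for c in cells])

    opt = optimizer or Adam(config.learning_rate, config.beta1, config.beta2, config.eps)
    rng = np.random.default_rng(config.seed)
    f, w = model.factors, model.weights
    grid = model.grid
    log = TrainLog(seed=config.seed)
    t0 = time.time()

    for epoch in range(config.epochs):
        order = rng.permutation(bins)
        pick = rng.integers(0, len(cells), size=len(order))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            sl = slice(start, start + config.batch_size)
            ci, g = pick[sl], order[sl]
            bi, ai = cell_b[ci], cell_a[ci]
            fi, mi, co = grid.multiscale_indices(g)
            X = np.concatenate(
                [f.biosample[bi], f.assay[ai], f.fine[fi], f.mid[mi], f.coarse[co]],
                axis=1,
            )
            y = Y[ci, g]
            pred, cache = _forward_cache(X, w)
            res = pred - y
            n = len(res)
            loss = float(res @ res) / n
            epoch_loss += loss * n
            net_grads, dX = _backward(cache, 2.0 * res / n, w)

            opt.step()
            if trainable.network:
                g_W1, g_b1, g_W2, g_b2, g_wout, g_bout = net_grads
                opt.dense("W1", w.W1, g_W1)
                opt.dense("b1", w.b1, g_b1)
                opt.dense("W2", w.W2, g_W2)
                opt.dense("b2", w.b2, g_b2)
                opt.dense("w_out", w.w_out, g_wout)
                w.b_out = opt.scalar("b_out", w.b_out, g_bout)

            cfg = model.config
            o0 = 0
            slices = []
            for name, dim, idx, enabled, row_filter, param in (
                ("biosample", cfg.d_biosample, bi, trainable.biosample,
                 trainable.biosample_rows, f.biosample),
                ("assay", cfg.d_assay, ai, trainable.assay,
                 trainable.assay_rows, f.assay),
                ("fine", cfg.d_fine, fi, trainable.genome, None, f.fine),
                ("mid", cfg.d_mid, mi, trainable.genome, None, f.mid),
                ("coarse", cfg.d_coarse, co, trainable.genome, None, f.coarse),
            ):
                dpart = dX[:, o0:o0 + dim]
                o0 += dim
                if not enabled:
                    continue
                rows, acc = _scatter_rows(idx, dpart, row_filter)
                opt.rows(name, param, rows, acc)

        epoch_loss /= len(order)
        if not np.isfinite(epoch_loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={epoch_loss!r} "
                f"(lr={config.learning_rate}, batch={config.batch_size})"
            )
        log.losses.append(epoch_loss)

    log.epochs = config.epochs
    log.wall_time = time.time() - t0
    return log


def train_stage1(model: Model, tensor: TrackTensor, config: TrainConfig) -> TrainLog:
    """Jointly train all parameters on the training (pilot) regions."""
    bins = model.grid.training_region_bins()
    return train(model, tensor, bins, config, TrainableGroups())


def train_stage2(model: Model, tensor: TrackTensor, config: TrainConfig,
                 chromosome: str) -> TrainLog:
    """Train only the genomic factor rows of one chromosome; the network,
    biosample, and assay parameters stay bit-identical."""
    bins = model.grid.bins_for_chromosome(chromosome)  # KeyError if unknown
    flags = TrainableGroups(network=False, biosample=False, assay=False, genome=True)
    return train(model, tensor, bins, config, flags)


def fit_model(
    model: Model,
    tensor: TrackTensor,
    stage1: TrainConfig,
    stage2: TrainConfig | None = None,
) -> list[TrainLog]:
    """Full pipeline: stage 1 on pilot regions, then stage 2 per chromosome
    when the pilot regions do not already cover the whole genome."""
    logs = [train_stage1(model, tensor, stage1)]
    covers_all = len(model.grid.training_region_bins()) == model.grid.n_bins
    if stage2 is not None and not covers_all:
        for i, chrom in enumerate(model.grid.chromosome_names):
            logs.append(train_stage2(model, tensor, replace(stage2, seed=stage2.seed + i + 1),
                                     chrom))
    return logs


def mse_on_cells(model: Model, tensor: TrackTensor, bins: np.ndarray | None = None,
                 cells=None) -> float:
    """Mean squared error of the model against observed cell vectors."""
    cells = list(cells) if cells is not None else tensor.observed_cells()
    if not cells:
        raise ValueError("no cells to evaluate")
    total, count = 0.0, 0
    for b, a in cells:
        pred = model.predict(b, a, bins=bins)
        obs = tensor.values[(b, a)]
        obs = obs if bins is None else obs[np.asarray(bins, dtype=np.int64)]
        d = pred - obs
        total += float(d @ d)
        count += len(d)
    return total / count
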
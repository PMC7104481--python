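"""The multi-scale deep tensor factorization model.

Each (biosample, assay, genomic bin) triple is embedded by concatenating
five latent-factor rows — biosample, assay, and genomic factors at fine,
mid, and coarse resolution — and decoded by a feed-forward network with two
ReLU hidden layers and a linear regression head.  Predictions live on the
arcsinh scale.

The concatenation order is fixed as (biosample, assay, fine, mid, coarse);
checkpoints store axis label lists, which are authoritative for the
index <-> identifier mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .grid import GenomicGrid


@dataclass(frozen=True)
class ModelConfig:
    """Latent dimensionalities and decoder width.

    Full-scale defaults: 32 factors per biosample, 256 per assay, 25 per
    fine (25 bp) position, 40 per mid (250 bp) block, 45 per coarse (5 kbp)
    block, and 2048 neurons in each hidden layer.
    """

    d_biosample: int = 32
    d_assay: int = 256
    d_fine: int = 25
    d_mid: int = 40
    d_coarse: int = 45
    hidden: int = 2048

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if int(v) <= 0:
                raise ValueError(f"{name} must be a positive integer")

    @property
    def d_input(self) -> int:
        return self.d_biosample + self.d_assay + self.d_fine + self.d_mid + self.d_coarse

    @classmethod
    def desk(cls) -> "ModelConfig":
        """A small configuration suitable for laptop-scale experiments."""
        return cls(d_biosample=4, d_assay=8, d_fine=5, d_mid=4, d_coarse=3, hidden=32)


@dataclass
class FactorSet:
    """Five latent-factor matrices (rows match the tensor/grid axes)."""

    biosample: np.ndarray  # (n_biosamples, d_biosample)
    assay: np.ndarray      # (n_assays, d_assay)
    fine: np.ndarray       # (n_fine_bins, d_fine)
    mid: np.ndarray        # (n_mid_blocks, d_mid)
    coarse: np.ndarray     # (n_coarse_blocks, d_coarse)

    def copy(self) -> "FactorSet":
        return FactorSet(*(getattr(self, f).copy() for f in FIELD_ORDER))

    def check_finite(self) -> None:
        for f in FIELD_ORDER:
            if not np.all(np.isfinite(getattr(self, f))):
                raise ValueError(f"non-finite entries in {f} factors")


FIELD_ORDER = ("biosample", "assay", "fine", "mid", "coarse")


@dataclass
class NetworkWeights:
    """Two hidden dense layers plus a linear output head."""

    W1: np.ndarray  # (d_input, hidden)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden, hidden)
    b2: np.ndarray  # (hidden,)
    w_out: np.ndarray  # (hidden,)
    b_out: float

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(
            self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy(),
            self.w_out.copy(), float(self.b_out),
        )


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_parameters(
    config: ModelConfig,
    n_biosamples: int,
    n_assays: int,
    grid: GenomicGrid,
    seed: int = 0,
) -> tuple[FactorSet, NetworkWeights]:
    """Seeded initialization: Glorot-uniform dense weights, zero biases,
    small symmetric-uniform embedding rows.  Identical seeds give
    bit-identical parameters."""
    rng = np.random.default_rng(seed)
    factors = FactorSet(
        biosample=rng.uniform(-0.05, 0.05, size=(n_biosamples, config.d_biosample)),
        assay=rng.uniform(-0.05, 0.05, size=(n_assays, config.d_assay)),
        fine=rng.uniform(-0.05, 0.05, size=(grid.n_bins, config.d_fine)),
        mid=rng.uniform(-0.05, 0.05, size=(grid.n_mid, config.d_mid)),
        coarse=rng.uniform(-0.05, 0.05, size=(grid.n_coarse, config.d_coarse)),
    )
    d_in, h = config.d_input, config.hidden
    weights = NetworkWeights(
        W1=_glorot_uniform(rng, d_in, h, (d_in, h)),
        b1=np.zeros(h),
        W2=_glorot_uniform(rng, h, h, (h, h)),
        b2=np.zeros(h),
        w_out=_glorot_uniform(rng, h, 1, (h,)),
        b_out=0.0,
    )
    return factors, weights


def new_embedding_row(d: int, rng: np.random.Generator) -> np.ndarray:
    """Initialization for a single appended factor row (matches init_parameters)."""
    return rng.uniform(-0.05, 0.05, size=(d,))


def embed(
    biosample_index,
    assay_index,
    bin_index,
    factors: FactorSet,
    grid: GenomicGrid,
) -> np.ndarray:
    """Concatenate the five factor rows for the given indices.

    Scalar indices give a 1-D vector of length d_input; array indices give
    a (n, d_input) matrix.
    """
    scalar = np.isscalar(bin_index)
    bi = np.atleast_1d(np.asarray(biosample_index, dtype=np.int64))
    ai = np.atleast_1d(np.asarray(assay_index, dtype=np.int64))
    gi = np.atleast_1d(np.asarray(bin_index, dtype=np.int64))
    n = max(len(bi), len(ai), len(gi))
    bi, ai, gi = np.broadcast_to(bi, (n,)), np.broadcast_to(ai, (n,)), np.broadcast_to(gi, (n,))
    if np.any(bi < 0) or np.any(bi >= len(factors.biosample)):
        raise IndexError("biosample index out of range")
    if np.any(ai < 0) or np.any(ai >= len(factors.assay)):
        raise IndexError("assay index out of range")
    fi, mi, ci = grid.multiscale_indices(gi)
    X = np.concatenate(
        [factors.biosample[bi], factors.assay[ai], factors.fine[fi],
         factors.mid[mi], factors.coarse[ci]],
        axis=1,
    )
    return X[0] if scalar and n == 1 else X


def forward(x: np.ndarray, weights: NetworkWeights):
    """Decode embedded input(s): ReLU hidden layers, linear output."""
    X = np.asarray(x, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != weights.W1.shape[0]:
        raise ValueError(
            f"input length {X.shape[1]} does not match d_input {weights.W1.shape[0]}"
        )
    h1 = np.maximum(X @ weights.W1 + weights.b1, 0.0)
    h2 = np.maximum(h1 @ weights.W2 + weights.b2, 0.0)
    out = h2 @ weights.w_out + weights.b_out
    return float(out[0]) if single else out


def predict_track(
    biosample_index: int,
    assay_index: int,
    factors: FactorSet,
    weights: NetworkWeights,
    grid: GenomicGrid,
    bins: np.ndarray | None = None,
    chunk: int = 65536,
) -> np.ndarray:
    """Predicted arcsinh-scale signal at every requested bin (default: all)."""
    if bins is None:
        bins = np.arange(grid.n_bins, dtype=np.int64)
    bins = np.asarray(bins, dtype=np.int64)
    out = np.empty(len(bins), dtype=np.float64)
    for start in range(0, len(bins), chunk):
        sl = slice(start, start + chunk)
        X = embed(biosample_index, assay_index, bins[sl], factors, grid)
        out[sl] = forward(X, weights)
    return out


@dataclass
class Model:
    """A grid-aware model bundle with label <-> index mapping and checkpoints."""

    grid: GenomicGrid
    biosamples: list[str]
    assays: list[str]
    config: ModelConfig
    factors: FactorSet
    weights: NetworkWeights

    @classmethod
    def initialize(
        cls,
        grid: GenomicGrid,
        biosamples: list[str],
        assays: list[str],
        config: ModelConfig | None = None,
        seed: int = 0,
    ) -> "Model":
        config = config or ModelConfig()
        factors, weights = init_parameters(config, len(biosamples), len(assays), grid, seed)
        return cls(grid, list(biosamples), list(assays), config, factors, weights)

    def copy(self) -> "Model":
        return Model(self.grid, list(self.biosamples), list(self.assays),
                     self.config, self.factors.copy(), self.weights.copy())

    def biosample_index(self, label: str) -> int:
        try:
            return self.biosamples.index(label)
        except ValueError:
            raise KeyError(f"unknown biosample {label!r}") from None

    def assay_index(self, label: str) -> int:
        try:
            return self.assays.index(label)
        except ValueError:
            raise KeyError(f"unknown assay {label!r}") from None

    def predict(self, biosample: str, assay: str, bins: np.ndarray | None = None) -> np.ndarray:
        return predict_track(
            self.biosample_index(biosample), self.assay_index(assay),
            self.factors, self.weights, self.grid, bins=bins,
        )

    # --- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        meta = {
            "config": self.config.__dict__,
            "grid": self.grid.to_dict(),
            "biosamples": self.biosamples,
            "assays": self.assays,
        }
        np.savez(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            f_biosample=self.factors.biosample,
            f_assay=self.factors.assay,
            f_fine=self.factors.fine,
            f_mid=self.factors.mid,
            f_coarse=self.factors.coarse,
            W1=self.weights.W1, b1=self.weights.b1,
            W2=self.weights.W2, b2=self.weights.b2,
            w_out=self.weights.w_out, b_out=np.float64(self.weights.b_out),
        )

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            factors = FactorSet(
                biosample=z["f_biosample"], assay=z["f_assay"],
                fine=z["f_fine"], mid=z["f_mid"], coarse=z["f_coarse"],
            )
            weights = NetworkWeights(
                W1=z["W1"], b1=z["b1"], W2=z["W2"], b2=z["b2"],
                w_out=z["w_out"], b_out=float(z["b_out"]),
            )
        return cls(
            grid=GenomicGrid.from_dict(meta["grid"]),
            biosamples=list(meta["biosamples"]),
            assays=list(meta["assays"]),
            config=ModelConfig(**meta["config"]),
            factors=factors,
            weights=weights,
        )
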
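import numpy as np
import pytest

from epitensor import GenomicGrid, Model, ModelConfig, TrackTensor


@pytest.fixture
def grid2():
    """Two small chromosomes, 25 bp bins, default block ratios."""
    return GenomicGrid([("chr1", 10_000), ("chr2", 7_500)])


@pytest.fixture
def tiny_grid():
    """One chromosome, 60 bins, small blocks."""
    return GenomicGrid([("chr1", 1_500)], bin_size=25, ratio_mid=5, ratio_coarse=20)


@pytest.fixture
def tiny_config():
    return ModelConfig(d_biosample=3, d_assay=4, d_fine=3, d_mid=2, d_coarse=2, hidden=8)


@pytest.fixture
def tiny_model(tiny_grid, tiny_config):
    return Model.initialize(tiny_grid, ["b0", "b1", "b2"], ["a0", "a1"],
                            tiny_config, seed=42)


@pytest.fixture
def tiny_tensor(tiny_grid, tiny_model):
    """Three observed cells with smooth positive signal."""
    rng = np.random.default_rng(0)
    g = np.arange(tiny_grid.n_bins)
    values = {}
    for i, cell in enumerate([("b0", "a0"), ("b1", "a0"), ("b1", "a1")]):
        values[cell] = 1.0 + 0.5 * np.sin(g / (3.0 + i)) + 0.1 * rng.normal(size=len(g))
    return TrackTensor(biosamples=["b0", "b1", "b2"], assays=["a0", "a1"], values=values)
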
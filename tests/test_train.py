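import numpy as np
import pytest

from epitensor import (
    GenomicGrid,
    Model,
    ModelConfig,
    TrackTensor,
    TrainConfig,
    TrainableGroups,
    embed,
    forward,
    mse_on_cells,
    sample_epoch,
    set_trainable,
    train,
    train_stage1,
    train_stage2,
)
from epitensor.simulate import SyntheticSpec, generate_compendium
from epitensor.train import _backward, _forward_cache


def snapshot(model):
    f, w = model.factors, model.weights
    return {
        "biosample": f.biosample.copy(), "assay": f.assay.copy(),
        "fine": f.fine.copy(), "mid": f.mid.copy(), "coarse": f.coarse.copy(),
        "W1": w.W1.copy(), "b1": w.b1.copy(), "W2": w.W2.copy(),
        "b2": w.b2.copy(), "w_out": w.w_out.copy(), "b_out": w.b_out,
    }


def changed(model, before):
    after = snapshot(model)
    return {k for k in before
            if not np.array_equal(np.atleast_1d(before[k]), np.atleast_1d(after[k]))}


class TestSampleEpoch:
    def test_single_cell_everywhere(self, tiny_tensor, tiny_grid):
        t = tiny_tensor.subset([("b0", "a0")])
        bi, ai, g = sample_epoch(t, tiny_grid, np.arange(10), seed=0)
        assert len(g) == 10
        assert set(zip(bi, ai)) == {(0, 0)}

    def test_each_bin_exactly_once(self, tiny_tensor, tiny_grid):
        region = np.arange(tiny_grid.n_bins)
        _, _, g = sample_epoch(tiny_tensor, tiny_grid, region, seed=1)
        assert sorted(g) == list(region)

    def test_cells_uniform_binomial(self, tiny_grid):
        values = {(b, a): np.zeros(tiny_grid.n_bins)
                  for b in ("b0", "b1") for a in ("a0", "a1")}
        t = TrackTensor(["b0", "b1"], ["a0", "a1"], values)
        region = np.arange(tiny_grid.n_bins)
        counts = np.zeros(4)
        for rep in range(10_000 // tiny_grid.n_bins + 1):
            bi, ai, _ = sample_epoch(t, tiny_grid, region, seed=100 + rep)
            counts += np.bincount(bi * 2 + ai, minlength=4)
        n = counts.sum()
        expected = n / 4
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - expected) < 3 * sigma)

    def test_seed_determinism(self, tiny_tensor, tiny_grid):
        a = sample_epoch(tiny_tensor, tiny_grid, np.arange(20), seed=7)
        b = sample_epoch(tiny_tensor, tiny_grid, np.arange(20), seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_no_cells_errors(self, tiny_grid):
        empty = TrackTensor(["b"], ["a"], {})
        with pytest.raises(ValueError):
            sample_epoch(empty, tiny_grid, np.arange(5), seed=0)


class TestGradients:
    def test_backward_matches_finite_differences(self, tiny_model, tiny_tensor):
        """Analytic gradients of the batch squared error agree with central
        finite differences for every parameter group."""
        model, grid = tiny_model, tiny_model.grid
        rng = np.random.default_rng(0)
        bi = rng.integers(0, 2, size=6)
        ai = rng.integers(0, 2, size=6)
        g = rng.integers(0, grid.n_bins, size=6)
        y = rng.normal(size=6)

        def loss():
            X = embed(bi, ai, g, model.factors, model.weights and model.grid)
            pred = forward(X, model.weights)
            r = pred - y
            return float(r @ r) / len(r)

        # analytic
        X = embed(bi, ai, g, model.factors, grid)
        pred, cache = _forward_cache(X, model.weights)
        res = pred - y
        net_grads, dX = _backward(cache, 2.0 * res / len(res), model.weights)
        g_W1, g_b1, g_W2, g_b2, g_wout, g_bout = net_grads

        eps = 1e-6
        checks = [
            (model.weights.W1, g_W1), (model.weights.b1, g_b1),
            (model.weights.W2, g_W2), (model.weights.b2, g_b2),
            (model.weights.w_out, g_wout),
        ]
        rng2 = np.random.default_rng(1)
        for param, grad in checks:
            flat_p, flat_g = param.ravel(), np.asarray(grad).ravel()
            for idx in rng2.choice(flat_p.size, size=min(5, flat_p.size), replace=False):
                orig = flat_p[idx]
                flat_p[idx] = orig + eps
                up = loss()
                flat_p[idx] = orig - eps
                down = loss()
                flat_p[idx] = orig
                num = (up - down) / (2 * eps)
                assert num == pytest.approx(flat_g[idx], rel=1e-4, abs=1e-8)

        # scalar output bias
        w = model.weights
        w.b_out += eps
        up = loss()
        w.b_out -= 2 * eps
        down = loss()
        w.b_out += eps
        assert (up - down) / (2 * eps) == pytest.approx(g_bout, rel=1e-4, abs=1e-8)

        # embedding gradient via dX for the first sample's biosample row
        d_b = model.config.d_biosample
        row = bi[0]
        grad_row = np.zeros(d_b)
        for k in range(len(bi)):
            if bi[k] == row:
                grad_row += dX[k, :d_b]
        for j in range(d_b):
            orig = model.factors.biosample[row, j]
            model.factors.biosample[row, j] = orig + eps
            up = loss()
            model.factors.biosample[row, j] = orig - eps
            down = loss()
            model.factors.biosample[row, j] = orig
            assert (up - down) / (2 * eps) == pytest.approx(grad_row[j], rel=1e-4,
                                                            abs=1e-8)


class TestTrainLoop:
    def test_zero_epochs_is_identity(self, tiny_model, tiny_tensor):
        before = snapshot(tiny_model)
        log = train(tiny_model, tiny_tensor, np.arange(tiny_model.grid.n_bins),
                    TrainConfig(epochs=0, batch_size=16))
        assert changed(tiny_model, before) == set()
        assert log.losses == []

    def test_loss_reproducible_bitwise(self, tiny_grid, tiny_config, tiny_tensor):
        logs = []
        for _ in range(2):
            m = Model.initialize(tiny_grid, ["b0", "b1", "b2"], ["a0", "a1"],
                                 tiny_config, seed=3)
            logs.append(train(m, tiny_tensor, np.arange(tiny_grid.n_bins),
                              TrainConfig(epochs=5, batch_size=16, seed=4)).losses)
        assert logs[0] == logs[1]

    def test_all_frozen_errors(self, tiny_model, tiny_tensor):
        with pytest.raises(ValueError):
            train(tiny_model, tiny_tensor, np.arange(10),
                  TrainConfig(epochs=1, batch_size=8),
                  set_trainable(network=False, biosample=False, assay=False,
                                genome=False))

    def test_partial_freeze_only_updates_flagged_group(self, tiny_model, tiny_tensor):
        before = snapshot(tiny_model)
        train(tiny_model, tiny_tensor, np.arange(tiny_model.grid.n_bins),
              TrainConfig(epochs=2, batch_size=16),
              set_trainable(network=False, biosample=False, assay=True, genome=False))
        assert changed(tiny_model, before) == {"assay"}

    def test_conditional_mean_with_frozen_zero_genome(self):
        """With genome factors zeroed and frozen, all bins share one
        embedding, so a single observed track is fit by its mean."""
        grid = GenomicGrid([("chr1", 50)])  # 2 bins
        config = ModelConfig(d_biosample=2, d_assay=2, d_fine=2, d_mid=2,
                             d_coarse=2, hidden=8)
        model = Model.initialize(grid, ["b"], ["a"], config, seed=0)
        model.factors.fine[:] = 0.0
        model.factors.mid[:] = 0.0
        model.factors.coarse[:] = 0.0
        tensor = TrackTensor(["b"], ["a"], {("b", "a"): np.array([1.0, 3.0])})
        train(model, tensor, np.arange(2),
              TrainConfig(epochs=800, batch_size=2, seed=1),
              set_trainable(genome=False))
        pred = model.predict("b", "a")
        assert pred[0] == pred[1]
        assert pred[0] == pytest.approx(2.0, abs=0.05)

    def test_convergence_on_tiny_noiseless_fixture(self):
        comp = generate_compendium(SyntheticSpec(
            n_bins=200, n_biosamples=4, n_assays=4, decoder="matched",
            noise_sd=0.0, observed_fraction=0.6, seed=5))
        model = Model.initialize(comp.grid, comp.tensor.biosamples,
                                 comp.tensor.assays, ModelConfig.desk(), seed=6)
        initial = mse_on_cells(model, comp.tensor)
        train(model, comp.tensor, np.arange(comp.grid.n_bins),
              TrainConfig(epochs=400, batch_size=32, seed=7))
        assert mse_on_cells(model, comp.tensor) < 0.05 * initial


class TestStages:
    @pytest.fixture
    def staged(self):
        grid = GenomicGrid([("chr1", 2000), ("chr2", 2000)],
                           training_regions={"chr1": [(0, 500)],
                                             "chr2": [(0, 500)]})
        rng = np.random.default_rng(2)
        values = {("b0", "a0"): rng.uniform(0, 2, grid.n_bins),
                  ("b1", "a0"): rng.uniform(0, 2, grid.n_bins)}
        tensor = TrackTensor(["b0", "b1"], ["a0"], values)
        model = Model.initialize(grid, ["b0", "b1"], ["a0"],
                                 ModelConfig.desk(), seed=8)
        return model, tensor

    def test_stage1_uses_training_regions_only(self, staged):
        model, tensor = staged
        before = snapshot(model)
        train_stage1(model, tensor, TrainConfig(epochs=2, batch_size=64, seed=0))
        # fine rows outside the pilot regions are untouched
        pilot = set(model.grid.training_region_bins().tolist())
        outside = [g for g in range(model.grid.n_bins) if g not in pilot]
        assert np.array_equal(model.factors.fine[outside],
                              before["fine"][outside])
        assert "W1" in changed(model, before)

    def test_stage2_freezes_everything_but_genome(self, staged):
        model, tensor = staged
        train_stage1(model, tensor, TrainConfig(epochs=2, batch_size=64, seed=0))
        before = snapshot(model)
        train_stage2(model, tensor, TrainConfig(epochs=2, batch_size=64, seed=1),
                     "chr1")
        assert changed(model, before) <= {"fine", "mid", "coarse"}

    def test_stage2_is_chromosome_local(self, staged):
        model, tensor = staged
        before = snapshot(model)
        train_stage2(model, tensor, TrainConfig(epochs=2, batch_size=64, seed=1),
                     "chr1")
        start, stop = model.grid.bin_range("chr2")
        assert np.array_equal(model.factors.fine[start:stop],
                              before["fine"][start:stop])
        start1, stop1 = model.grid.bin_range("chr1")
        assert not np.array_equal(model.factors.fine[start1:stop1],
                                  before["fine"][start1:stop1])

    def test_stage2_unknown_chromosome(self, staged):
        model, tensor = staged
        with pytest.raises(KeyError):
            train_stage2(model, tensor, TrainConfig(epochs=1, batch_size=64), "chrX")
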
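import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epitensor import (
    FoldAssignment,
    PeakLabelSet,
    TrackTensor,
    aggregate_to_windows,
    average_activity,
    average_precision,
    epr,
    evaluate_compendium,
    filter_ambiguous,
    greedy_fold_partition,
    mse_global,
    mse_region,
    mse_top1,
    paired_t,
    relative_reduction,
)
from epitensor.metrics import average_activity_imputer, compare_reports, track_metrics


# --- brute-force oracles (kept deliberately naive) -----------------------

def mse_oracle(a, b):
    total = 0.0
    for x, y in zip(a, b):
        total += (x - y) ** 2
    return total / len(a)


def top1_oracle(observed, imputed, selector):
    k = int(np.ceil(0.01 * len(selector)))
    order = sorted(range(len(selector)), key=lambda i: (-selector[i], i))
    idx = order[:k]
    return mse_oracle([observed[i] for i in idx], [imputed[i] for i in idx])


def ap_oracle(scores, labels):
    # sweep every distinct threshold, step-wise precision x recall increments
    thresholds = sorted(set(scores), reverse=True)
    n_pos = sum(labels)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        sel = [i for i, s in enumerate(scores) if s >= t]
        tp = sum(labels[i] for i in sel)
        precision = tp / len(sel)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def epr_oracle(scores, labels, include_ties=True):
    n_pos = sum(labels)
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    cutoff = scores[order[n_pos - 1]]
    sel = ([i for i in range(len(scores)) if scores[i] >= cutoff]
           if include_ties else order[:n_pos])
    return sum(labels[i] for i in sel) / len(sel)


def paired_t_oracle(a, b):
    d = [x - y for x, y in zip(a, b)]
    n = len(d)
    mean = sum(d) / n
    sd = (sum((x - mean) ** 2 for x in d) / (n - 1)) ** 0.5
    t = mean / (sd / n ** 0.5)
    p = 2 * sps.t.sf(abs(t), n - 1)
    return t, p


class TestMseFamily:
    def test_identical_is_zero(self):
        v = np.arange(5.0)
        assert mse_global(v, v) == 0.0

    def test_hand_example(self):
        assert mse_global([0.0, 1.0], [1.0, 1.0]) == 0.5

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 50))
            a, b = rng.normal(size=n), rng.normal(size=n)
            assert mse_global(a, b) == pytest.approx(mse_oracle(a, b), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse_global([1.0], [1.0, 2.0])

    def test_top1_unique_max_selects_single_position(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=100)
        imp = rng.normal(size=100)
        i = int(np.argmax(obs))
        assert mse_top1(obs, imp, by="observed") == pytest.approx(
            (obs[i] - imp[i]) ** 2)

    def test_top1_identical_tracks_zero_both_ways(self):
        v = np.random.default_rng(2).normal(size=300)
        assert mse_top1(v, v, by="observed") == 0.0
        assert mse_top1(v, v, by="imputed") == 0.0

    def test_top1_matches_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(100, 400))
            obs = np.round(rng.normal(size=n), 1)  # rounded -> frequent ties
            imp = rng.normal(size=n)
            for by, sel in (("observed", obs), ("imputed", imp)):
                assert mse_top1(obs, imp, by=by) == pytest.approx(
                    top1_oracle(obs, imp, sel), abs=1e-12)

    def test_top1_needs_100_positions(self):
        with pytest.raises(ValueError):
            mse_top1(np.zeros(99), np.zeros(99))

    def test_region_full_mask_equals_global(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert mse_region(a, b, np.arange(50)) == pytest.approx(mse_global(a, b))

    def test_region_single_bin(self):
        a, b = np.array([1.0, 2.0]), np.array([1.0, 5.0])
        assert mse_region(a, b, np.array([1])) == 9.0

    def test_region_matches_oracle_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            a, b = rng.normal(size=n), rng.normal(size=n)
            mask = rng.choice(n, size=int(rng.integers(1, n)), replace=False)
            assert mse_region(a, b, mask) == pytest.approx(
                mse_oracle(a[mask], b[mask]), abs=1e-12)

    def test_region_empty_mask(self):
        with pytest.raises(ValueError):
            mse_region([1.0], [1.0], np.array([], dtype=int))


class TestPairedT:
    def test_identical_vectors(self):
        assert paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_closed_form_example(self):
        t, p = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert t == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-4)
        assert t == pytest.approx(3.4641, abs=1e-4)
        assert p == pytest.approx(2 * sps.t.sf(3.4641, 2), abs=1e-4)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            a, b = rng.normal(size=n), rng.normal(size=n)
            t, p = paired_t(a, b)
            t0, p0 = paired_t_oracle(a, b)
            assert t == pytest.approx(t0, abs=1e-10)
            assert p == pytest.approx(p0, abs=1e-10)

    def test_zero_variance_nonzero_mean(self):
        t, p = paired_t([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert np.isinf(t) and p == 0.0

    def test_relative_reduction(self):
        assert relative_reduction(0.0807, 0.0653) == pytest.approx(0.1908, abs=1e-4)


class TestAverageActivity:
    def test_single_track_verbatim(self):
        t = TrackTensor(["b0"], ["a0"], {("b0", "a0"): np.array([1.0, 2.0])})
        assert np.array_equal(average_activity(t, "a0"), [1.0, 2.0])

    def test_positionwise_mean(self):
        t = TrackTensor(["b0", "b1"], ["a0"],
                        {("b0", "a0"): np.array([1.0, 1.0]),
                         ("b1", "a0"): np.array([3.0, 5.0])})
        assert np.array_equal(average_activity(t, "a0"), [2.0, 3.0])

    def test_excluding_everything_errors(self):
        t = TrackTensor(["b0"], ["a0"], {("b0", "a0"): np.zeros(2)})
        with pytest.raises(ValueError):
            average_activity(t, "a0", exclude_biosamples={"b0"})


class TestWindows:
    def test_constant_track(self):
        agg = aggregate_to_windows(np.full(40, 2.5))
        assert np.all(agg == 2.5)

    def test_first_window_mean_of_eight_bins(self):
        v = np.arange(1.0, 41.0)
        agg = aggregate_to_windows(v)
        assert agg[0] == pytest.approx(np.mean(v[:8]))
        assert agg[0] == pytest.approx(4.5)

    def test_adjacent_windows_share_six_bins(self):
        # window at offset 50 bp covers bins 2..10; offset 0 covers 0..8
        v = np.random.default_rng(7).normal(size=64)
        agg = aggregate_to_windows(v)
        assert agg[1] == pytest.approx(np.mean(v[2:10]))

    def test_truncation_at_chromosome_end(self):
        v = np.arange(10.0)
        agg = aggregate_to_windows(v)
        assert agg[-1] == pytest.approx(np.mean(v[8:]))

    def test_window_smaller_than_bin(self):
        with pytest.raises(ValueError):
            aggregate_to_windows(np.zeros(10), bin_size=25, window=10)


class TestAmbiguousFiltering:
    def test_no_ambiguous_is_identity(self):
        labels = PeakLabelSet(np.array([1, 0, 1, 0]))
        s, y = filter_ambiguous(np.arange(4.0), labels)
        assert len(s) == 4 and set(y) <= {0, 1}

    def test_ambiguous_dropped_from_both(self):
        lab = PeakLabelSet(np.array([1, -1, 0, -1, 0, 1, -1, 0, -1, 1]))
        s, y = filter_ambiguous(np.arange(10.0), lab)
        assert len(s) == len(y) == 6
        assert set(y) <= {0, 1}

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError):
            filter_ambiguous(np.zeros(3), PeakLabelSet(np.array([-1, -1, -1])))

    def test_code_mapping(self):
        lab = PeakLabelSet.from_codes(["B", "U", "A"])
        assert lab.labels.tolist() == [1, 0, -1]
        with pytest.raises(ValueError):
            PeakLabelSet.from_codes(["B", "X"])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == 1.0

    def test_hand_computed_steps(self):
        ap = average_precision([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert ap == pytest.approx(1.0 * 0.5 + (2 / 3) * 0.5)
        assert ap == pytest.approx(0.8333, abs=1e-4)

    def test_matches_threshold_sweep_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.uniform(size=n), 1)  # ties likely
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[0], labels[-1] = 1, 0
            assert average_precision(scores, labels) == pytest.approx(
                ap_oracle(list(scores), list(labels)), abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(9)
        for _ in range(20):
            scores = rng.normal(size=50)
            labels = rng.integers(0, 2, size=50)
            if labels.sum() in (0, 50):
                labels[0], labels[-1] = 1, 0
            assert average_precision(scores, labels) == pytest.approx(
                sklearn_metrics.average_precision_score(labels, scores), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0], labels[-1] = 1, 0
        assert average_precision(np.exp(scores), labels) == pytest.approx(
            average_precision(scores, labels))

    def test_degenerate_labels_error(self):
        with pytest.raises(ValueError):
            average_precision([0.1, 0.2], [1, 1])


class TestEpr:
    def test_perfect_ranking(self):
        assert epr([0.9, 0.8, 0.1, 0.0], [1, 1, 0, 0]) == 1.0

    def test_hand_count(self):
        assert epr([0.9, 0.8, 0.1, 0.05], [1, 0, 1, 0]) == 0.5

    def test_bounds_on_random_scores(self):
        # per-instance EPR lies in (0, 1]; on average over random scorings
        # it cannot fall below the positive base rate
        rng = np.random.default_rng(11)
        vals, base = [], []
        for _ in range(100):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            scores = rng.normal(size=n)
            val = epr(scores, labels)
            assert 0.0 <= val <= 1.0
            vals.append(val)
            base.append(labels.mean())
        assert np.mean(vals) >= np.mean(base) - 0.05

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = np.round(rng.uniform(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            for ties in (True, False):
                assert epr(scores, labels, include_ties=ties) == pytest.approx(
                    epr_oracle(list(scores), list(labels), ties), abs=1e-12)

    def test_tie_policy_flag(self):
        scores = [0.9, 0.5, 0.5, 0.5, 0.1]
        labels = [1, 1, 0, 0, 0]
        # P=2; cutoff score 0.5 -> ties enlarge the set to 4 windows
        assert epr(scores, labels, include_ties=True) == pytest.approx(0.5)
        assert epr(scores, labels, include_ties=False) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[0] = 1
        assert epr(3 * scores + 1, labels) == pytest.approx(epr(scores, labels))

    def test_no_positives_error(self):
        with pytest.raises(ValueError):
            epr([0.5], [0])


class TestFoldPartition:
    def test_counter_walk_without_shuffling(self):
        exps = [("A", "x"), ("A", "y"), ("A", "z"), ("B", "x"), ("B", "y")]
        folds = greedy_fold_partition(exps, k=2, shuffle=False)
        assert [folds.folds[e] for e in exps] == [0, 1, 0, 1, 0]

    def test_balanced_within_one(self):
        rng = np.random.default_rng(14)
        for trial in range(20):
            exps = [(f"b{rng.integers(8)}", f"a{i}") for i in range(int(rng.integers(5, 60)))]
            exps = list(dict.fromkeys(exps))
            folds = greedy_fold_partition(exps, k=5, seed=trial)
            sizes = folds.fold_sizes()
            assert sizes.max() - sizes.min() <= 1

    def test_deterministic_under_seed(self):
        exps = [(f"b{i % 4}", f"a{i}") for i in range(23)]
        f1 = greedy_fold_partition(exps, seed=3)
        f2 = greedy_fold_partition(exps, seed=3)
        assert f1.folds == f2.folds

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            greedy_fold_partition([("b", "a")], k=1)

    def test_coverage_on_constructed_instance(self):
        # 6 biosamples x 6 assays fully crossed: every fold's training
        # complement must contain every assay and biosample
        exps = [(f"b{i}", f"a{j}") for i in range(6) for j in range(6)]
        folds = greedy_fold_partition(exps, k=5, seed=0)
        cov = folds.coverage()
        assert (cov["train_assays"] == 6).all()
        assert (cov["train_biosamples"] == 6).all()


class TestEvaluateCompendium:
    @pytest.fixture
    def small_setup(self):
        from epitensor import GenomicGrid
        grid = GenomicGrid([("chr1", 3000)])  # 120 bins, enough for top-1%
        rng = np.random.default_rng(15)
        biosamples = [f"b{i}" for i in range(4)]
        assays = ["a0", "a1"]
        values = {(b, a): np.abs(rng.normal(size=grid.n_bins)) + 0.1
                  for b in biosamples for a in assays}
        tensor = TrackTensor(biosamples, assays, values)
        folds = greedy_fold_partition(sorted(values), k=2, seed=0)
        return tensor, folds

    def test_perfect_imputer_scores_zero(self, small_setup):
        tensor, folds = small_setup
        report = evaluate_compendium(lambda tt, b, a: tensor.values[(b, a)],
                                     tensor, folds)
        for m in ("mseGlobal", "mse1obs", "mse1imp"):
            assert (report.per_track[m] == 0.0).all()

    def test_average_activity_imputer_matches_direct_baseline(self, small_setup):
        tensor, folds = small_setup
        report = evaluate_compendium(average_activity_imputer, tensor, folds)
        row = report.per_track.iloc[0]
        cell = (row["biosample"], row["assay"])
        train = tensor.subset([c for c in folds.training_cells(row["fold"])])
        expected = mse_global(tensor.values[cell],
                              average_activity(train, cell[1], {cell[0]}))
        assert row["mseGlobal"] == pytest.approx(expected)

    def test_lonely_assay_skipped_with_warning(self):
        values = {("b0", "a0"): np.ones(120) * 0.5,
                  ("b1", "a0"): np.ones(120)}
        tensor = TrackTensor(["b0", "b1"], ["a0"], values)
        # both tracks of the assay share a fold: the training complement
        # never contains a counterpart track of that assay
        folds = FoldAssignment(folds={("b0", "a0"): 0, ("b1", "a0"): 0}, k=2)
        with pytest.warns(UserWarning):
            report = evaluate_compendium(lambda tt, b, a: tt.values[sorted(tt.values)[0]],
                                         tensor, folds)
        assert len(report.per_track) == 0

    def test_compare_reports_win_counts(self, small_setup):
        tensor, folds = small_setup
        perfect = evaluate_compendium(lambda tt, b, a: tensor.values[(b, a)],
                                      tensor, folds)
        base = evaluate_compendium(average_activity_imputer, tensor, folds)
        table = compare_reports(perfect, base)
        row = table[table["metric"] == "mseGlobal"].iloc[0]
        assert row["assays_won"] == row["assays_total"]
        assert row["method_mean"] == 0.0
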
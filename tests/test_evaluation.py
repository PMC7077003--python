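"""Metrics, bootstrap CIs, ROC/PR and binned recall."""

import numpy as np
import pytest
from scipy import stats

from dmsbench.errors import RefusalError
from dmsbench.evaluation import (
    PairedScores,
    binned_recall,
    bootstrap_ci,
    confusion_at_threshold,
    mse,
    pair_scores,
    pearson,
    pr_curve,
    regression_line,
    roc_and_auc,
    spearman,
)
from dmsbench.predictors import MethodSpec, PredictionSet
from dmsbench.score_processing import normalize_dataset

from conftest import make_dataset, pairwise_auc_oracle, spearman_bruteforce


def paired(x, p, labels=None):
    keys = [("P", i + 1, "A", "V") for i in range(len(x))]
    return PairedScores(np.asarray(x, float), np.asarray(p, float), keys,
                        labels=None if labels is None else np.asarray(labels))


class TestPairScores:
    def make_norm(self, scores):
        ds = make_dataset(scores)
        return normalize_dataset(ds)

    def pred_for(self, keys, values=None):
        spec = MethodSpec("m", 0, 1, default_threshold=0.5)
        vals = values if values is not None else [0.5] * len(keys)
        scores = dict(zip(keys, vals))
        return PredictionSet(spec, scores, unit_scores=dict(scores))

    def test_largest_common_subset(self):
        norm = self.make_norm([(1, "A", "V", -1.0), (1, "A", "G", -2.0),
                               (2, "L", "P", -0.5)])
        pred = self.pred_for([("P1", 1, "A", "V"), ("P1", 2, "L", "P"),
                              ("P1", 2, "L", "Q")], [0.1, 0.2, 0.3])
        pair = pair_scores(norm, pred, "deleterious")
        assert pair.n == 2
        assert pair.keys == [("P1", 1, "A", "V"), ("P1", 2, "L", "P")]

    def test_disjoint_keys_refused(self):
        norm = self.make_norm([(1, "A", "V", -1.0)])
        pred = self.pred_for([("P1", 5, "K", "R")])
        with pytest.raises(RefusalError, match="empty"):
            pair_scores(norm, pred, "deleterious")

    def test_identical_keys_keeps_full_side(self):
        norm = self.make_norm([(i, "A", "V", -float(i)) for i in range(1, 8)])
        pred = self.pred_for([("P1", i, "A", "V") for i in range(1, 8)])
        assert pair_scores(norm, pred, "deleterious").n == 7


class TestCorrelations:
    def test_identity_gives_rho_one(self):
        x = [0.1, 0.4, 0.7, 0.9]
        assert spearman(paired(x, x)).estimate == pytest.approx(1.0)

    def test_reversal_gives_rho_minus_one(self):
        x = np.array([0.1, 0.4, 0.7, 0.9])
        assert spearman(paired(x, 1 - x)).estimate == pytest.approx(-1.0)

    def test_worked_example_four_points(self):
        """x=(1,2,3,4), p=(1,3,2,4): one swapped pair, rho = 0.8."""
        res = spearman(paired([1, 2, 3, 4], [1, 3, 2, 4]))
        assert res.estimate == pytest.approx(0.8, abs=1e-12)

    def test_matches_bruteforce_on_tie_free_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(4, 9)
            x = rng.permutation(n).astype(float)
            p = rng.permutation(n).astype(float)
            got = spearman(paired(x, p)).estimate
            assert got == pytest.approx(spearman_bruteforce(x, p), abs=1e-12)

    def test_constant_vector_is_refused_not_zero(self):
        with pytest.raises(RefusalError, match="constant"):
            spearman(paired([1, 2, 3], [5, 5, 5]))
        with pytest.raises(RefusalError):
            pearson(paired([2, 2, 2], [1, 2, 3]))

    def test_pearson_affine_invariance_and_sign(self):
        x = np.linspace(0, 1, 10)
        assert pearson(paired(x, 2 * x + 1)).estimate == pytest.approx(1.0)
        assert pearson(paired([0, 1, 0.5], [1, 0, 0.5])).estimate == \
            pytest.approx(-1.0)


class TestMse:
    def test_examples(self):
        x = np.array([0.1, 0.2, 0.3])
        assert mse(paired(x, x)).estimate == 0.0
        assert mse(paired(x, x + 0.1)).estimate == pytest.approx(0.01)
        assert mse(paired([0, 1], [1, 1])).estimate == pytest.approx(0.5)


class TestBootstrapCi:
    def test_degenerate_perfect_correlation(self):
        x = np.linspace(0, 1, 30)
        lo, hi = bootstrap_ci(spearman, paired(x, x), reps=100, seed=1)
        assert (lo, hi) == (1.0, 1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(2)
        pr = paired(rng.random(100), rng.random(100))
        assert bootstrap_ci(mse, pr, reps=200, seed=9) == \
            bootstrap_ci(mse, pr, reps=200, seed=9)

    def test_fast_path_agrees_with_generic_loop(self):
        """The vectorized resampling for the core metrics must match the
        naive per-resample recomputation bit-for-bit at the same seed."""
        rng = np.random.default_rng(3)
        pr = paired(rng.random(60), rng.random(60))
        for metric in (spearman, pearson, mse):
            fast = bootstrap_ci(metric, pr, reps=100, seed=4)
            slow = bootstrap_ci(lambda q, _m=metric: _m(q), pr,
                                reps=100, seed=4)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(5)
        x = rng.random(300)
        p = x + rng.normal(0, 0.3, 300)
        pr = paired(x, p)
        est = spearman(pr).estimate
        lo, hi = bootstrap_ci(spearman, pr, reps=500, seed=6)
        assert lo <= est <= hi


class TestRocAndAuc:
    def test_perfect_separation(self):
        labels = [0, 0, 0, 1, 1]
        scores = [0.1, 0.2, 0.3, 0.8, 0.9]
        roc = roc_and_auc(labels, scores, reps=10, seed=0)
        assert roc.auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        roc = roc_and_auc([0, 1, 0, 1], [0.5] * 4, reps=10, seed=0)
        assert roc.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(8, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.integers(0, 6, n) / 5.0  # coarse grid forces ties
            roc = roc_and_auc(labels, scores, reps=2, seed=0)
            assert roc.auc == pytest.approx(
                pairwise_auc_oracle(labels, scores), abs=1e-12)

    def test_complement_symmetry_tie_free(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        scores = rng.permutation(30) / 30.0
        a = roc_and_auc(labels, scores, reps=0, seed=0).auc
        b = roc_and_auc(labels, -scores, reps=0, seed=0).auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_refused(self):
        with pytest.raises(RefusalError, match="both classes"):
            roc_and_auc([1, 1, 1], [0.1, 0.2, 0.3], reps=10, seed=0)

    def test_curve_monotone(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        roc = roc_and_auc(labels, rng.random(50), reps=2, seed=0)
        fprs, tprs = zip(*roc.points)
        assert all(a <= b for a, b in zip(fprs, fprs[1:]))
        assert all(a <= b for a, b in zip(tprs, tprs[1:]))


class TestPrCurve:
    def test_perfect_separation_reaches_one_one(self):
        points = pr_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert (1.0, 1.0) in points

    def test_all_positive_precision_one_everywhere(self):
        points = pr_curve([1, 1, 1], [0.2, 0.5, 0.9])
        assert all(prec == 1.0 for _, prec in points)

    def test_hand_counted_confusion(self):
        labels = [1, 0, 1, 0]
        scores = [0.9, 0.8, 0.7, 0.1]
        counts = confusion_at_threshold(labels, scores, 0.65)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 1, 0, 1)
        assert counts.precision == pytest.approx(2 / 3)
        assert counts.recall == 1.0
        assert any(rec == 1.0 and prec == pytest.approx(2 / 3)
                   for rec, prec in pr_curve(labels, scores))

    def test_no_positives_refused(self):
        with pytest.raises(RefusalError):
            pr_curve([0, 0], [0.1, 0.2])


class TestBinnedRecall:
    def test_all_effect_calls_flat_recall(self):
        rng = np.random.default_rng(0)
        pr = paired(rng.random(100), rng.random(100))
        br = binned_recall(pr, ["effect"] * 100, n_bins=20)
        assert np.all(br.recall == 1.0)
        assert np.all(br.adjusted_recall == 0.0)

    def test_step_predictor_splits_bins(self):
        x = np.arange(100) / 100.0
        calls = x >= 0.5
        br = binned_recall(paired(x, x), calls, n_bins=20)
        assert np.all(br.recall[:10] == 0.0)
        assert np.all(br.recall[10:] == 1.0)
        assert br.adjusted_recall[0] == 0.0

    def test_remainder_spread_over_lowest_bins(self):
        pr = paired(np.arange(41) / 41.0, np.zeros(41))
        br = binned_recall(pr, [False] * 41, n_bins=20)
        assert sorted(br.bin_count.tolist()) == [2] * 19 + [3]
        assert br.bin_count[0] == 3  # remainder goes to the lowest bin
        assert br.bin_count.sum() == 41

    def test_equal_width_binning_alternative(self):
        x = np.concatenate([np.full(30, 0.1), np.full(10, 0.9)])
        calls = x > 0.5
        br = binned_recall(paired(x, x), calls, n_bins=4, binning="width")
        assert br.bin_count.tolist() == [30, 0, 0, 10]
        assert br.recall[0] == 0.0 and br.recall[3] == 1.0
        assert np.isnan(br.recall[1])

    def test_fewer_variants_than_bins_refused(self):
        with pytest.raises(RefusalError, match="n_bins"):
            binned_recall(paired([0.1, 0.2], [0, 0]), [0, 0], n_bins=20)


class TestRegressionLine:
    def test_identity_and_constant(self):
        x = np.linspace(0, 1, 9)
        assert regression_line(paired(x, x)) == pytest.approx((1.0, 0.0))
        assert regression_line(paired(x, np.full(9, 0.5))) == \
            pytest.approx((0.0, 0.5))

    def test_two_point_line(self):
        assert regression_line(paired([0, 1], [0.2, 0.8])) == \
            pytest.approx((0.6, 0.2))

    def test_constant_x_refused(self):
        with pytest.raises(RefusalError, match="constant"):
            regression_line(paired([0.5, 0.5], [0.1, 0.9]))


def test_spearman_invariant_under_monotone_transforms():
    rng = np.random.default_rng(4)
    x = rng.random(200)
    p = rng.random(200)
    base = spearman(paired(x, p)).estimate
    assert spearman(paired(np.sqrt(x), p ** 3)).estimate == \
        pytest.approx(base, abs=1e-12)
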
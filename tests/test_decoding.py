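"""Balancing, selection, normalization, ANN training, CV structure, chance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.linear_model import LogisticRegression

from prestim.epochs_io import FACE, NOFACE
from prestim.features import FeatureDescriptor, FeatureSet
from prestim.decoding import (
    DecodingConfig,
    downsample_balance,
    empirical_chance,
    evaluate,
    nested_cv_run,
    normalize01,
    pam_aggregate,
    select_by_threshold,
    train_ann,
    ttest_rank,
)


def labels_of(n_face, n_noface):
    return np.array([FACE] * n_face + [NOFACE] * n_noface, dtype=object)


class TestDownsampleBalance:
    def test_subject1_counts_give_66_per_class(self):
        idx = downsample_balance(labels_of(67, 193), n_folds=6)
        lab = labels_of(67, 193)[idx]
        assert int((lab == FACE).sum()) == 66
        assert int((lab == NOFACE).sum()) == 66

    def test_already_balanced_divisible_classes_kept_whole(self):
        idx = downsample_balance(labels_of(100, 100), n_folds=5)
        assert len(idx) == 200

    def test_seeded_determinism_and_no_replacement(self):
        labels = labels_of(20, 50)
        a = downsample_balance(labels, 6, seed=3)
        b = downsample_balance(labels, 6, seed=3)
        assert np.array_equal(a, b)
        assert len(set(a)) == len(a)

    def test_minority_class_smaller_than_fold_count_rejected(self):
        with pytest.raises(ValueError):
            downsample_balance(labels_of(4, 50), n_folds=6)


class TestTtestRank:
    def test_identical_groups_give_p_one(self):
        x = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        p = ttest_rank(x, labels_of(3, 3))
        assert p[0] == pytest.approx(1.0)

    def test_textbook_pooled_t_on_three_plus_three_points(self):
        # hand calculation: means 2 and 5, pooled var 1, t = -3/sqrt(2/3)
        x = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        p = ttest_rank(x, labels_of(3, 3))
        t_hand = -3.0 / np.sqrt(2.0 / 3.0)
        assert t_hand == pytest.approx(-3.674, abs=5e-4)
        assert p[0] == pytest.approx(2 * stats.t.sf(abs(t_hand), df=4), rel=1e-12)
        assert p[0] == pytest.approx(0.0214, abs=5e-4)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((60, 500))
        p = ttest_rank(x, labels_of(30, 30))
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_zero_variance_conventions(self):
        x = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 2.0], [1.0, 2.0]])
        p = ttest_rank(x, labels_of(2, 2))
        assert p[0] == 1.0  # equal constant groups
        assert p[1] == 0.0  # different constant groups

    def test_single_sample_class_rejected(self):
        with pytest.raises(ValueError):
            ttest_rank(np.zeros((3, 2)), labels_of(1, 2))


class TestSelectByThreshold:
    def test_strictly_below_threshold(self):
        p = np.array([0.001, 0.03, 0.2])
        assert list(select_by_threshold(p, 0.025)) == [0]
        assert list(select_by_threshold(p, 0.05)) == [0, 1]
        assert list(select_by_threshold(p, 0.2)) == [0, 1]  # ties excluded

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50), st.integers(0, 9))
    @settings(max_examples=50, deadline=None)
    def test_selection_nested_in_threshold(self, p_values, k):
        p = np.array(p_values)
        low, high = 0.005 * (k + 1), 0.005 * (k + 3)
        assert set(select_by_threshold(p, low)) <= set(select_by_threshold(p, high))


class TestNormalize01:
    def test_train_column_maps_to_unit_interval(self):
        (out,) = normalize01(np.array([[2.0], [4.0]]))
        assert list(out[:, 0]) == [0.0, 1.0]

    def test_out_of_range_test_values_clipped(self):
        train = np.array([[2.0], [4.0]])
        _, test = normalize01(train, np.array([[5.0], [1.0]]))
        assert list(test[:, 0]) == [1.0, 0.0]

    def test_constant_train_column_maps_to_half(self):
        train = np.array([[3.0], [3.0]])
        tr, te = normalize01(train, np.array([[0.0], [9.0]]))
        assert np.all(tr == 0.5) and np.all(te == 0.5)

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_outputs_always_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        train = rng.normal(0, 10, (5, 3))
        other = rng.normal(0, 20, (4, 3))
        tr, ot = normalize01(train, other)
        assert tr.min() >= 0 and tr.max() <= 1
        assert ot.min() >= 0 and ot.max() <= 1


def separable_toy(n=20, gap=3.0, seed=1):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(0, 0.3, (n, 2)), rng.normal(gap, 0.3, (n, 2))])
    y = labels_of(n, n)
    return x, y


class TestTrainAnn:
    def test_reaches_full_accuracy_on_linearly_separable_clusters(self):
        x, y = separable_toy()
        # independent separability oracle
        assert LogisticRegression().fit(x, y.astype(str)).score(x, y.astype(str)) == 1.0
        model = train_ann((x, y), (x, y), DecodingConfig(max_epochs=500), seed=0)
        assert float((model.predict(x) == y).mean()) == 1.0

    def test_single_class_validation_set_rejected(self):
        x, y = separable_toy()
        with pytest.raises(ValueError, match="lacks a class"):
            train_ann((x, y), (x[:5], y[:5]), DecodingConfig(), seed=0)

    def test_seeded_determinism(self):
        x, y = separable_toy()
        cfg = DecodingConfig(max_epochs=200)
        a = train_ann((x, y), (x, y), cfg, seed=5).predict(x)
        b = train_ann((x, y), (x, y), cfg, seed=5).predict(x)
        assert np.array_equal(a, b)

    def test_non_finite_inputs_rejected(self):
        x, y = separable_toy()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train_ann((x, y), (x, y), DecodingConfig(), seed=0)


class TestEvaluate:
    def test_confusion_count_arithmetic(self):
        truth = labels_of(33, 33)
        pred = truth.copy()
        pred[:3] = NOFACE  # 3 missed faces
        pred[33:38] = FACE  # 5 false alarms
        m = evaluate(pred, truth)
        assert m.sensitivity == pytest.approx(100 * 30 / 33, abs=5e-3)
        assert m.specificity == pytest.approx(100 * 28 / 33, abs=5e-3)
        assert m.accuracy == pytest.approx(100 * 58 / 66, abs=5e-3)

    def test_perfect_predictions(self):
        truth = labels_of(5, 5)
        assert evaluate(truth, truth) == (100.0, 100.0, 100.0)

    def test_degenerate_all_face_predictor(self):
        truth = labels_of(5, 5)
        m = evaluate(labels_of(10, 0), truth)
        assert (m.sensitivity, m.specificity) == (100.0, 0.0)

    def test_absent_class_rate_is_nan(self):
        truth = labels_of(4, 0)
        m = evaluate(truth, truth)
        assert np.isnan(m.specificity) and m.sensitivity == 100.0


class TestEmpiricalChance:
    def test_approaches_fifty_percent_for_large_n(self):
        # normal-approximation oracle: 50 + 100*z_alpha/(2*sqrt(n)) percent
        n = 10**6
        approx = 50.0 + 100.0 * stats.norm.isf(0.05) / (2.0 * np.sqrt(n))
        assert empirical_chance(n, 0.05) == pytest.approx(approx, abs=0.005)
        assert empirical_chance(n, 0.05) == pytest.approx(50.08, abs=0.01)

    def test_single_evaluation_requires_perfection(self):
        assert empirical_chance(1, 0.05) == 100.0

    @pytest.mark.parametrize("n_eval", [10, 66, 132, 501])
    def test_defining_binomial_tail_inequalities(self, n_eval):
        # exhaustive pmf summation around the returned cutoff
        chance = empirical_chance(n_eval, 0.05)
        k = int(round(chance / 100.0 * n_eval))
        def tail(j):  # P(X > j) by full summation
            return sum(stats.binom.pmf(i, n_eval, 0.5) for i in range(j + 1, n_eval + 1))
        assert tail(k) < 0.05
        assert tail(k - 1) >= 0.05

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            empirical_chance(100, 0.0)


class TestPamAggregate:
    def test_two_subject_mean_and_sd(self):
        out = pam_aggregate([70.0, 80.0])
        assert out["accuracy_mean"] == pytest.approx(75.0)
        assert out["accuracy_sd"] == pytest.approx(7.071, abs=5e-4)

    def test_single_subject_sd_is_zero(self):
        out = pam_aggregate([73.2])
        assert out["accuracy_mean"] == 73.2 and out["accuracy_sd"] == 0.0

    def test_invariant_to_subject_order(self):
        a = pam_aggregate([60.0, 70.0, 85.0])
        b = pam_aggregate([85.0, 60.0, 70.0])
        assert a == b


def random_feature_set(n_face=67, n_noface=193, n_features=300, seed=0):
    """Null features: label-independent noise (a permutation oracle)."""
    rng = np.random.default_rng(seed)
    descriptors = tuple(
        FeatureDescriptor("single", f"e{i}", "alpha", 0, (-738.0, -728.0))
        for i in range(n_features)
    )
    return FeatureSet(
        rng.standard_normal((n_face + n_noface, n_features)),
        descriptors,
        labels_of(n_face, n_noface),
    )


QUICK = dict(max_epochs=60, seed=9)


class TestNestedCvRun:
    def test_rep_fold_bookkeeping(self):
        f = random_feature_set()
        res = nested_cv_run(f, DecodingConfig(n_reps=2, n_folds=6, **QUICK))
        assert res.model_count == 12
        assert {(r.rep, r.fold) for r in res.records} == {
            (i, j) for i in range(2) for j in range(6)
        }
        assert res.n_balanced == 132

    def test_balanced_folds_make_accuracy_mean_of_rates(self):
        f = random_feature_set()
        res = nested_cv_run(f, DecodingConfig(n_reps=1, n_folds=6, **QUICK))
        for r in res.records:
            assert r.accuracy == pytest.approx((r.sensitivity + r.specificity) / 2)

    def test_folds_disjoint_cover_balanced_set_and_never_leak(self):
        f = random_feature_set()
        calls = []
        nested_cv_run(
            f, DecodingConfig(n_reps=2, n_folds=6, **QUICK),
            audit=lambda rep, fold, tr, va, te: calls.append((rep, tr, va, te)),
        )
        by_rep = {}
        for rep, tr, va, te in calls:
            # within a fold: train, validation and test trials are disjoint
            assert not (set(tr) & set(va)) and not (set(tr) | set(va)) & set(te)
            by_rep.setdefault(rep, []).append(set(te))
        for folds in by_rep.values():
            assert len(folds) == 6
            union = set().union(*folds)
            assert sum(len(s) for s in folds) == len(union) == 132

    def test_selected_feature_count_monotone_in_threshold(self):
        f = random_feature_set(seed=4)
        counts = []
        for thr in (0.005, 0.02, 0.05, 0.2):
            res = nested_cv_run(
                f, DecodingConfig(n_reps=1, n_folds=6, p_threshold=thr, **QUICK)
            )
            counts.append(np.mean([len(r.selected) for r in res.records]))
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_null_features_decode_at_chance(self):
        # permutation oracle: label-independent features, 25 rebalancings
        f = random_feature_set(seed=1)
        res = nested_cv_run(f, DecodingConfig(n_reps=25, n_folds=6, **QUICK))
        assert res.model_count == 150
        assert abs(res.mean_accuracy - 50.0) <= 3.0

    def test_seeded_run_is_reproducible(self):
        f = random_feature_set()
        cfg = DecodingConfig(n_reps=1, n_folds=6, **QUICK)
        a, b = nested_cv_run(f, cfg), nested_cv_run(f, cfg)
        assert a.records == b.records

    def test_empty_selection_falls_back_to_ten_best(self, caplog):
        f = random_feature_set(n_face=30, n_noface=30, n_features=20, seed=2)
        res = nested_cv_run(
            f, DecodingConfig(n_reps=1, n_folds=6, p_threshold=1e-12, **QUICK)
        )
        assert all(len(r.selected) == 10 for r in res.records)
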
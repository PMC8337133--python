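import numpy as np
import pytest

from fsvmsr import (
    CS1,
    FSVMHyperParams,
    apply_scheme,
    cross_validate,
    grid_search,
    repeated_cv_ttest,
    roc_auc,
    score,
    stratified_kfold,
    welch_ttest,
)
from fsvmsr.errors import (
    DegenerateStatisticError,
    DimensionMismatchError,
    InvalidParameterError,
)
from fsvmsr.evaluation import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID


class TestScore:
    def test_hand_counted_example(self):
        r = score([1, 2, 2], [1, 1, 2], c=2)
        assert r.whole_acc == pytest.approx(200 / 3)
        assert r.per_class_acc == (pytest.approx(50.0), pytest.approx(100.0))
        np.testing.assert_array_equal(r.confusion, [[1, 1], [0, 1]])

    def test_perfect_and_disjoint(self):
        assert score([1, 2], [1, 2], 2).whole_acc == 100.0
        assert score([2, 1], [1, 2], 2).whole_acc == 0.0

    def test_absent_class_reported_missing_not_zero(self):
        r = score([1, 1], [1, 1], c=2)
        assert r.per_class_acc[1] is None

    def test_whole_acc_is_weighted_mean_of_per_class(self, rng):
        for _ in range(20):
            c = int(rng.integers(2, 5))
            n = int(rng.integers(5, 40))
            truth = rng.integers(1, c + 1, n)
            pred = rng.integers(1, c + 1, n)
            r = score(pred, truth, c)
            num = sum(
                m * a for m, a in zip(r.M_per_class, r.per_class_acc)
                if a is not None
            )
            assert r.whole_acc == pytest.approx(num / r.M)
            assert r.M == sum(r.M_per_class)
            np.testing.assert_array_equal(r.confusion.sum(axis=1), r.M_per_class)

    def test_length_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            score([1], [1, 2], 2)


class TestStratifiedKFold:
    def test_balanced_small_case(self):
        y = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        folds = stratified_kfold(y, 5, seed=0)
        for f in folds:
            assert sorted(y[f]) == [1, 2]

    def test_determinism(self):
        y = np.repeat([1, 2, 3], [10, 7, 4])
        a = stratified_kfold(y, 5, seed=9)
        b = stratified_kfold(y, 5, seed=9)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa, fb)

    def test_study_profile_fold_balance(self):
        y = np.repeat([1, 2], [42, 17])
        folds = stratified_kfold(y, 10, seed=4)
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(59))
        for f in folds:
            c1 = int(np.sum(y[f] == 1))
            c2 = int(np.sum(y[f] == 2))
            assert c1 in (4, 5) and c2 in (1, 2)

    def test_k_exceeds_n(self):
        with pytest.raises(InvalidParameterError):
            stratified_kfold(np.array([1, 2, 1]), 4, seed=0)


class TestCrossValidate:
    def test_separable_fixture_is_perfect(self, separable_blobs):
        rep = cross_validate(
            separable_blobs, FSVMHyperParams(C=10.0, gamma=0.5), k=4, seed=0
        )
        assert rep.mean_whole_acc == 100.0

    def test_svm_equals_fsvmsr_on_clean_data(self, separable_blobs):
        params = FSVMHyperParams(C=10.0, gamma=0.5)
        a = cross_validate(separable_blobs, params, k=4, seed=1, method="fsvm_sr")
        b = cross_validate(separable_blobs, params, k=4, seed=1, method="svm")
        assert abs(a.mean_whole_acc - b.mean_whole_acc) <= 5.0

    def test_leave_one_out_matches_manual_loop(self):
        from fsvmsr import Dataset, fit_multiclass, predict
        from fsvmsr.data_model import fit_standardizer

        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(2, 1, (3, 2)), rng.normal(-2, 1, (3, 2))])
        ds = Dataset(X, [1, 1, 1, 2, 2, 2], ("a", "b"))
        params = FSVMHyperParams(C=5.0, gamma=0.5)
        rep = cross_validate(ds, params, k=6, seed=0, method="svm")
        # brute-force LOO
        correct = 0
        for i in range(6):
            tr = np.delete(np.arange(6), i)
            std = fit_standardizer(ds.subset(tr))
            tr_ds = Dataset(
                std.transform(ds.features[tr]), ds.labels[tr], ds.feature_names
            )
            model = fit_multiclass(tr_ds, np.ones(5), params)
            pred, _ = predict(model, std.transform(ds.features[i][None, :]))
            correct += int(pred[0] == ds.labels[i])
        assert rep.mean_whole_acc == pytest.approx(100.0 * correct / 6)

    def test_report_aggregates_recomputable(self, separable_blobs):
        rep = cross_validate(
            separable_blobs, FSVMHyperParams(C=2.0, gamma=0.25), k=4, seed=5
        )
        whole = np.array([fr.whole_acc for fr in rep.fold_results])
        assert rep.mean_whole_acc == pytest.approx(whole.mean())
        assert rep.sd_whole_acc == pytest.approx(whole.std(ddof=1))


class TestGridSearch:
    def test_default_grid_dimensions(self):
        assert len(DEFAULT_C_GRID) == 16 and len(DEFAULT_GAMMA_GRID) == 16
        assert DEFAULT_C_GRID[0] == 2.0**-5 and DEFAULT_C_GRID[-1] == 2.0**10
        assert DEFAULT_GAMMA_GRID[0] == 2.0**-10 and DEFAULT_GAMMA_GRID[-1] == 2.0**5

    def test_single_cell_grid(self, separable_blobs):
        rep = grid_search(
            separable_blobs, k=4, seed=0, C_range=(2.0,), gamma_range=(0.5,)
        )
        assert (rep.best_C, rep.best_gamma) == (2.0, 0.5)
        assert len(rep.grid) == 1

    def test_separable_best_is_smallest_c_tie_winner(self, separable_blobs):
        C_range = (1.0, 4.0, 16.0)
        g_range = (0.25, 1.0)
        rep = grid_search(
            separable_blobs, k=4, seed=0, C_range=C_range, gamma_range=g_range,
            method="svm",
        )
        assert rep.best_mean_acc == 100.0
        perfect = [(C, g) for C, g, m, _ in rep.grid if m == 100.0]
        assert (rep.best_C, rep.best_gamma) == min(perfect)

    def test_traversal_order_invariance(self, separable_blobs):
        a = grid_search(separable_blobs, k=4, seed=0,
                        C_range=(1.0, 8.0), gamma_range=(0.25, 1.0))
        b = grid_search(separable_blobs, k=4, seed=0,
                        C_range=(8.0, 1.0), gamma_range=(1.0, 0.25))
        assert (a.best_C, a.best_gamma, a.best_mean_acc) == (
            b.best_C, b.best_gamma, b.best_mean_acc
        )


class TestRocAuc:
    def test_perfect_and_anti_ordered(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, -1, -1])
        assert auc == 1.0
        auc, _ = roc_auc([0.1, 0.2, 0.9, 0.8], [1, 1, -1, -1])
        assert auc == 0.0

    def test_four_point_worked_example(self):
        auc, _ = roc_auc([0.9, 0.8, 0.7, 0.6], [1, -1, 1, -1])
        assert auc == pytest.approx(0.75)

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = rng.choice(np.linspace(0, 1, 11), n)  # force ties
            truth = np.where(rng.random(n) < 0.5, 1, -1)
            if len(set(truth)) < 2:
                truth[0] = -truth[0]
            auc, _ = roc_auc(scores, truth)
            pos, neg = scores[truth == 1], scores[truth == -1]
            u = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            )
            assert auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(50)
        truth = np.where(rng.random(50) < 0.4, 1, -1)
        auc, _ = roc_auc(scores, truth)
        assert auc == pytest.approx(roc_auc_score(truth, scores))

    def test_roc_points_monotone(self, rng):
        scores = rng.standard_normal(30)
        truth = np.where(rng.random(30) < 0.5, 1, -1)
        _, pts = roc_auc(scores, truth)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            roc_auc([0.1, 0.2], [1, 1])


class TestWelchTTest:
    def test_identical_streams_give_p_one(self):
        a = np.array([80.0, 81.0, 79.0, 80.5])
        rep = welch_ttest(a, a.copy())
        assert rep.t_stat == 0.0 and rep.p_value == pytest.approx(1.0)

    def test_constant_but_different_streams_flagged(self):
        rep = welch_ttest(np.full(5, 80.0), np.full(5, 70.0))
        assert rep.degenerate and rep.p_value == 0.0

    def test_separated_normals_significant(self):
        rng = np.random.default_rng(99)
        a = rng.normal(80, 2, 20)
        b = rng.normal(70, 2, 20)
        rep = welch_ttest(a, b)
        assert rep.p_value < 0.05
        # scipy reference is itself the implementation; verify the t stat
        # against the closed-form Welch formula
        se = np.sqrt(a.var(ddof=1) / 20 + b.var(ddof=1) / 20)
        assert rep.t_stat == pytest.approx((a.mean() - b.mean()) / se)

    def test_repeated_cv_self_comparison(self, separable_blobs):
        params = FSVMHyperParams(C=5.0, gamma=0.5)
        rep = repeated_cv_ttest(
            separable_blobs, params, params, method_a="svm", method_b="svm",
            repeats=3, k=4, base_seed=0,
        )
        assert rep.p_value == pytest.approx(1.0)
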
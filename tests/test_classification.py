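"""Binary labeling, feature screening, SVM scoring, LOOCV, ROC/AUC,
operating point, performance metrics."""

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import minimize

from hwnraman import (
    SvmParams,
    binarize,
    choose_operating_point,
    feature_pvalues,
    loocv,
    performance_report,
    roc_and_auc,
    select_features,
    train_and_score,
)
from hwnraman.classification import NEGATIVE_LABEL, POSITIVE_LABEL


def pairwise_concordance_auc(scores, y01):
    """O(n^2) Mann-Whitney oracle: P(score_pos > score_neg), ties count 1/2."""
    scores = np.asarray(scores, float)
    y01 = np.asarray(y01)
    pos = scores[y01 == 1]
    neg = scores[y01 == 0]
    wins = halves = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                halves += 1
    return (wins + 0.5 * halves) / (len(pos) * len(neg))


class TestBinarize:
    def test_label_mapping(self):
        out = binarize(["normal", "infiltrated", "dense_cancer"])
        assert list(out) == [NEGATIVE_LABEL, NEGATIVE_LABEL, POSITIVE_LABEL]

    @pytest.mark.parametrize("f,expected", [
        (0.0, NEGATIVE_LABEL), (0.60, NEGATIVE_LABEL), (0.601, POSITIVE_LABEL),
    ])
    def test_fraction_threshold(self, f, expected):
        assert binarize([f])[0] == expected

    def test_empty_input(self):
        assert binarize([]).size == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            binarize(["gray_matter"])


class TestFeaturePvalues:
    def test_perfectly_separating_column_has_minimum_p(self, rng):
        y = np.array([0, 0, 0, 1, 1, 1])
        X = rng.normal(size=(6, 5))
        X[:, 2] = y * 10.0  # label indicator scaled
        p = feature_pvalues(X, y)
        assert np.argmin(p) == 2

    def test_constant_column_convention(self, rng):
        y = np.array([0, 0, 1, 1])
        X = rng.normal(size=(4, 3))
        X[:, 1] = 7.0
        assert feature_pvalues(X, y)[1] == 1.0

    def test_matches_pointbiserial_and_pooled_ttest(self, rng):
        y = np.array([0, 0, 0, 0, 1, 1, 1])
        X = rng.normal(size=(7, 6))
        p = feature_pvalues(X, y)
        for j in range(6):
            # closed-form t transform of the point-biserial correlation
            r, p_corr = sps.pointbiserialr(y, X[:, j])
            t_p = sps.ttest_ind(X[y == 0, j], X[y == 1, j], equal_var=True).pvalue
            assert p[j] == pytest.approx(p_corr, rel=1e-9)
            assert p[j] == pytest.approx(t_p, rel=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            feature_pvalues(rng.normal(size=(4, 3)), np.zeros(4))


class TestSelectFeatures:
    def test_all_columns(self):
        p = np.array([0.5, 0.01, 0.2])
        np.testing.assert_array_equal(select_features(p, 3), [0, 1, 2])

    def test_single_smallest(self):
        np.testing.assert_array_equal(select_features(np.array([0.5, 0.01, 0.2]), 1), [1])

    def test_tie_broken_by_lower_index(self):
        p = np.array([0.3, 0.1, 0.1, 0.05])
        np.testing.assert_array_equal(select_features(p, 2), [1, 3])

    def test_matches_sort_oracle(self, rng):
        p = rng.uniform(size=50)
        got = set(select_features(p, 10))
        expected = set(np.argsort(p)[:10])
        assert got == expected

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range(self, k):
        with pytest.raises(ValueError):
            select_features(np.array([0.1, 0.2, 0.3]), k)


def _dual_svm_oracle(X, y_signed, C=1.0):
    """Tiny linear-SVM dual solved with a generic constrained optimizer."""
    n = len(y_signed)
    Q = (y_signed[:, None] * y_signed[None, :]) * (X @ X.T)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    res = minimize(
        neg_dual, np.full(n, 0.1), method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ y_signed},
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    w = (a * y_signed) @ X
    sv = (a > 1e-6) & (a < C - 1e-6)
    b = np.mean(y_signed[sv] - X[sv] @ w)
    return w, b


class TestTrainAndScore:
    def test_separable_toy_signs(self):
        X_train = np.array([[-1.0], [-1.2], [-0.8], [1.0], [1.1], [0.9]])
        y = ["non_diagnostic"] * 3 + ["dense_cancer"] * 3
        scores = train_and_score(X_train, y, np.array([[-2.0], [2.0]]),
                                 SvmParams(n_features=1))
        assert scores[0] < 0 < scores[1]

    def test_training_point_as_test(self):
        X = np.array([[0.0, -2.0], [0.1, -1.8], [-0.1, -2.2],
                      [0.0, 2.0], [0.1, 2.2], [-0.1, 1.8]])
        y = [0, 0, 0, 1, 1, 1]
        scores = train_and_score(X, y, X, SvmParams(n_features=2))
        assert np.all(np.sign(scores) == np.array([-1, -1, -1, 1, 1, 1]))

    def test_matches_dual_qp_oracle(self):
        # fixed 6-point 2-D dataset, linear kernel, C = 1, no standardization
        X = np.array([[1.0, 1.5], [2.0, 1.0], [1.5, 2.5],
                      [-1.0, -1.0], [-2.0, -0.5], [-1.5, -2.0]])
        y = [1, 1, 1, 0, 0, 0]
        y_signed = np.array([1, 1, 1, -1, -1, -1], float)
        X_test = np.array([[0.5, 0.5], [-0.5, -1.0], [3.0, 0.0]])
        w, b = _dual_svm_oracle(X, y_signed, C=1.0)
        expected = X_test @ w + b
        got = train_and_score(X, y, X_test, SvmParams(n_features=2, standardize=False))
        np.testing.assert_allclose(got, expected, atol=1e-4)

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            train_and_score(np.zeros((3, 2)), [1, 1, 1], np.zeros((1, 2)))


class TestLOOCV:
    def _toy(self, rng, n=10, p=8):
        X = rng.normal(size=(n, p))
        y = np.array([0, 1] * (n // 2))
        X[:, 0] += 3 * y
        return X, y

    def test_manual_fold_enumeration_n4(self, rng):
        X = rng.normal(size=(4, 5))
        y = np.array([0, 0, 1, 1])
        params = SvmParams(n_features=3)
        cv = loocv(X, y, params)
        for i in range(4):
            mask = np.arange(4) != i
            manual = train_and_score(X[mask], y[mask], X[i], params)[0]
            assert cv.scores[i] == pytest.approx(manual, rel=1e-12)

    def test_row_permutation_invariance(self, rng):
        X, y = self._toy(rng)
        cv = loocv(X, y, SvmParams(n_features=4))
        perm = rng.permutation(len(y))
        cv_perm = loocv(X[perm], y[perm], SvmParams(n_features=4))
        np.testing.assert_allclose(cv_perm.scores, cv.scores[perm], atol=1e-9)

    def test_separable_cohort_all_correct(self, rng):
        X, y = self._toy(rng, n=16)
        X[:, 0] = (y - 0.5) * 20  # huge margin
        cv = loocv(X, y, SvmParams(n_features=2))
        assert np.all((cv.scores > 0) == (y == 1))

    def test_singleton_class_fold_uses_majority_fallback(self, rng):
        X = rng.normal(size=(5, 4))
        y = np.array([0, 0, 0, 0, 1])
        cv = loocv(X, y, SvmParams(n_features=2))
        assert cv.degenerate_folds == (4,)
        assert cv.scores[4] == -1.0  # majority class is negative

    def test_global_selection_mode_runs(self, rng):
        X, y = self._toy(rng)
        cv = loocv(X, y, SvmParams(n_features=4, selection="global"))
        assert "selection=global" in cv.provenance


class TestRocAuc:
    def test_perfect_ordering(self):
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        roc = roc_and_auc(scores, y)
        assert roc.auc == pytest.approx(1.0)
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0

    def test_symmetric_interleaving_gives_half(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 1, 1, 0])
        assert roc_and_auc(scores, y).auc == pytest.approx(0.5)

    def test_monotone_curve(self, rng):
        scores = rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        roc = roc_and_auc(scores, y)
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_trapezoid_equals_pairwise_concordance(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 50))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            y = rng.integers(0, 2, size=n)
            y[:2] = [0, 1]
            auc = roc_and_auc(scores, y).auc
            assert auc == pytest.approx(pairwise_concordance_auc(scores, y), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=80)
        y = rng.integers(0, 2, size=80)
        y[:2] = [0, 1]
        assert roc_and_auc(scores, y).auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_auc(np.array([1.0, 2.0]), np.array([1, 1]))


class TestOperatingPoint:
    def test_ideal_corner_wins(self):
        from hwnraman.classification import RocCurve

        roc = RocCurve(fpr=np.array([0.0, 0.0, 1.0]), tpr=np.array([0.0, 1.0, 1.0]),
                       thresholds=np.array([np.inf, 0.5, -np.inf]), auc=1.0)
        th, fpr, tpr = choose_operating_point(roc)
        assert (fpr, tpr) == (0.0, 1.0) and th == 0.5

    def test_distance_comparison(self):
        from hwnraman.classification import RocCurve

        roc = RocCurve(fpr=np.array([0.1, 0.4]), tpr=np.array([0.8, 0.9]),
                       thresholds=np.array([1.0, 0.0]), auc=0.8)
        _, fpr, tpr = choose_operating_point(roc)
        assert (fpr, tpr) == (0.1, 0.8)  # 0.2236 < 0.4123

    def test_degenerate_tie_prefers_higher_tpr(self):
        from hwnraman.classification import RocCurve

        roc = RocCurve(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
                       thresholds=np.array([np.inf, -np.inf]), auc=0.5)
        _, fpr, tpr = choose_operating_point(roc)
        assert (fpr, tpr) == (1.0, 1.0)


class TestPerformanceReport:
    def test_all_correct(self):
        scores = np.array([-1.0, -2.0, 1.0, 2.0])
        y = np.array([0, 0, 1, 1])
        r = performance_report(scores, y, threshold=0.0)
        assert r.accuracy == r.sensitivity == r.specificity == 1.0

    def test_stated_confusion_counts(self):
        # scores engineered to yield TP=99 FN=25 TN=94 FP=11 at threshold 0
        y = np.array([1] * 124 + [0] * 105)
        scores = np.concatenate([
            np.ones(99), -np.ones(25), -np.ones(94), np.ones(11),
        ])
        r = performance_report(scores, y, threshold=0.0)
        assert (r.tp, r.fn, r.tn, r.fp) == (99, 25, 94, 11)
        assert r.accuracy == pytest.approx((99 + 94) / 229)
        assert r.sensitivity == pytest.approx(99 / 124)
        assert r.specificity == pytest.approx(94 / 105)

    def test_all_predicted_positive(self):
        scores = np.ones(6)
        y = np.array([1, 1, 0, 0, 0, 1])
        r = performance_report(scores, y, threshold=0.0)
        assert r.sensitivity == 1.0 and r.specificity == 0.0
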
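"""PLS-DA: NIPALS fit, VIP normalization, OLS equivalence, CV selection."""

import numpy as np
import pandas as pd
import pytest

from mbomics import (
    DataError,
    cv_select_lv,
    fit_plsda,
    grouped_stratified_folds,
    predict_plsda,
)


def _autoscale(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def _separable(n=100, p=8, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
    X = rng.normal(size=(n, p))
    X[:, 0] += gap * y
    return pd.DataFrame(_autoscale(X)), y


class TestFit:
    def test_separable_data_perfect_training_accuracy(self):
        X, y = _separable()
        model = fit_plsda(X, y, 1)
        labels, _ = predict_plsda(model, X)
        assert (labels == np.where(y == 1, "case", "control")).all()

    def test_identical_response_columns_all_vip_one(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, size=40).astype(float)
        yc = y - y.mean()
        X = pd.DataFrame(np.tile(yc[:, None], (1, 5)), columns=list("abcde"))
        model = fit_plsda(X, y, 1)
        assert np.allclose(model.vip, 1.0, atol=1e-10)

    def test_informative_analyte_has_max_vip(self):
        rng = np.random.default_rng(2)
        n = 400
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        X = rng.normal(size=(n, 10))
        X[:, 3] += 1.5 * y
        model = fit_plsda(pd.DataFrame(_autoscale(X)), y, 1)
        assert model.vip.idxmax() == 3

    def test_vip_mean_square_is_one(self, autoscaled_frame):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=len(autoscaled_frame))
        for n_lv in (1, 3, 5):
            model = fit_plsda(autoscaled_frame, y, n_lv)
            assert (model.vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_scores_orthogonal(self, autoscaled_frame):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=len(autoscaled_frame))
        model = fit_plsda(autoscaled_frame, y, 4)
        G = model.scores.to_numpy().T @ model.scores.to_numpy()
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_full_rank_pls_matches_ols(self):
        """With n_lv = p <= n-1, PLS regression equals OLS on the same coding."""
        rng = np.random.default_rng(5)
        n, p = 50, 6
        y = rng.integers(0, 2, size=n).astype(float)
        X = pd.DataFrame(_autoscale(rng.normal(size=(n, p))))
        model = fit_plsda(X, y, p)
        yc = y - y.mean()
        beta, *_ = np.linalg.lstsq(X.to_numpy(), yc, rcond=None)
        y_ols = X.to_numpy() @ beta + y.mean()
        _, y_pls = predict_plsda(model, X)
        assert np.allclose(y_pls, y_ols, atol=1e-6)

    def test_matches_sklearn_pls_regression(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(12)
        n, p = 80, 15
        y = rng.integers(0, 2, size=n).astype(float)
        X = pd.DataFrame(_autoscale(rng.normal(size=(n, p))))
        for n_lv in (1, 2, 4):
            ours = fit_plsda(X, y, n_lv)
            ref = PLSRegression(n_components=n_lv, scale=False).fit(X.to_numpy(), y)
            _, y_ours = predict_plsda(ours, X)
            y_ref = ref.predict(X.to_numpy()).ravel()
            assert np.allclose(y_ours, y_ref, atol=1e-8)

    def test_single_class_rejected(self, autoscaled_frame):
        with pytest.raises(DataError, match="single class"):
            fit_plsda(autoscaled_frame, np.ones(len(autoscaled_frame)), 1)

    def test_n_lv_out_of_range(self, autoscaled_frame):
        y = np.r_[np.ones(30), np.zeros(30)]
        with pytest.raises(DataError, match="n_lv"):
            fit_plsda(autoscaled_frame, y, 13)


class TestPredict:
    def test_boundary_tie_goes_to_case(self):
        X, y = _separable(n=40, p=3)
        model = fit_plsda(X, y, 1)
        model.coefficients[:] = 0.0
        model.y_mean = 0.5
        labels, y_hat = predict_plsda(model, X)
        assert np.allclose(y_hat, 0.5)
        assert (labels == "case").all()

    def test_zero_rows_predict_training_class_mix(self):
        X, y = _separable(n=60, p=4, seed=6)
        model = fit_plsda(X, y, 2)
        zeros = pd.DataFrame(np.zeros((3, 4)), columns=X.columns)
        _, y_hat = predict_plsda(model, zeros)
        assert np.allclose(y_hat, y.mean())

    def test_analyte_mismatch_errors(self):
        X, y = _separable(n=40, p=3)
        model = fit_plsda(X, y, 1)
        with pytest.raises(DataError, match="lacks analyte"):
            predict_plsda(model, X.rename(columns={0: "other"}))


class TestCvSelect:
    def test_null_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(7)
        n = 200
        X = pd.DataFrame(_autoscale(rng.normal(size=(n, 50))))
        y = rng.integers(0, 2, size=n)
        subjects = [f"u{i}" for i in range(n)]
        _, report = cv_select_lv(X, y, subjects, max_lv=4, folds=5, seed=7)
        assert abs(report["cv_accuracy"].max() / 100 - 0.5) <= 0.12

    def test_separable_data_selects_few_lvs(self):
        X, y = _separable(n=120, p=20, gap=5.0, seed=8)
        subjects = [f"u{i}" for i in range(len(y))]
        best, report = cv_select_lv(X, y, subjects, max_lv=8, folds=6, seed=8)
        assert best <= 3
        assert report.loc[best, "cv_accuracy"] >= 95.0

    def test_tie_prefers_fewest_lvs(self):
        X, y = _separable(n=60, p=5, gap=8.0, seed=9)
        subjects = [f"u{i}" for i in range(len(y))]
        best, report = cv_select_lv(X, y, subjects, max_lv=5, folds=5, seed=9)
        ties = report.index[report["cv_accuracy"] == report["cv_accuracy"].max()]
        assert best == ties.min()

    def test_deterministic_given_seed(self):
        X, y = _separable(n=80, p=10, seed=10)
        subjects = [f"u{i // 2}" for i in range(len(y))]  # adjacent pairs share subject & class
        r1 = cv_select_lv(X, y, subjects, max_lv=4, folds=5, seed=3)
        r2 = cv_select_lv(X, y, subjects, max_lv=4, folds=5, seed=3)
        assert r1[0] == r2[0]
        pd.testing.assert_frame_equal(r1[1], r2[1])


class TestGroupedFolds:
    def test_subjects_never_split_and_classes_balanced(self):
        rng = np.random.default_rng(11)
        subjects = [f"u{i // 2}" for i in range(80)]  # two samples per subject
        labels = np.array([(1 if int(s[1:]) % 2 else 0) for s in subjects])
        folds = grouped_stratified_folds(labels, subjects, folds=4, seed=0)
        seen = {}
        for f, idx in enumerate(folds):
            for i in idx:
                assert seen.setdefault(subjects[i], f) == f
        sizes = [len(idx) for idx in folds]
        assert max(sizes) - min(sizes) <= 4

    def test_too_many_folds_errors(self):
        labels = [1, 1, 0, 0]
        subjects = ["a", "b", "c", "d"]
        with pytest.raises(DataError, match="fewer than"):
            grouped_stratified_folds(labels, subjects, folds=3, seed=0)

    def test_conflicting_subject_labels_rejected(self):
        with pytest.raises(DataError, match="both class labels"):
            grouped_stratified_folds([1, 0], ["a", "a"], folds=2, seed=0)
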
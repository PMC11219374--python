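"""SO-CovSel-LDA: CovSel oracle equivalence, orthogonalization, enumeration,
redundancy elimination, LDA geometry, and grid selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mbomics import (
    AnalyteBlock,
    DataError,
    MultiBlockDataset,
    SimConfig,
    covsel,
    enumerate_block_orders,
    fit_lda,
    fit_so_covsel_lda,
    generate_multiblock,
    grid_select,
    orthogonalize_block,
    predict_so_covsel,
    preprocess_dataset,
)


def brute_force_covsel(X, y, n_select):
    """Independent oracle: literal argmax-of-squared-covariance with explicit
    projection deflation, recomputed from scratch each step."""
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    n = X.shape[0]
    chosen = []
    for _ in range(n_select):
        best = (-1.0, None)
        for j in range(X.shape[1]):
            if j in chosen:
                continue
            c = (X[:, j] @ y / (n - 1)) ** 2
            if c > best[0]:
                best = (c, j)
        if best[0] < 1e-12:
            break
        j = best[1]
        chosen.append(j)
        t = X[:, j].copy()
        tt = t @ t
        if tt < 1e-12:
            break
        P = np.eye(n) - np.outer(t, t) / tt
        X = P @ X
        y = P @ y
    return chosen


class TestCovsel:
    def test_picks_column_with_max_covariance(self):
        X = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1.0]])
        y = np.array([1, 1, -1, -1.0])
        assert covsel(X, y, 1) == [0]
        assert covsel(X, X[:, 1].copy(), 1) == [1]

    def test_duplicate_column_never_selected_twice(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=30)
        y = x1 + rng.normal(scale=0.1, size=30)
        X = np.column_stack([x1, x1, rng.normal(size=30)])
        picks = covsel(X, y - y.mean(), 2)
        assert picks[0] == 0
        assert 1 not in picks  # deflation annihilates the duplicate

    def test_early_stop_on_no_covariance(self):
        X = np.column_stack([np.array([1, 1, -1, -1.0]), np.array([1, -1, 1, -1.0])])
        y = X[:, 0].copy()
        picks = covsel(X, y, 2)
        assert picks == [0]  # second column is orthogonal to the deflated response

    def test_matches_brute_force_oracle_on_200_seeded_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(6, 15))
            p = int(rng.integers(2, 9))
            k = int(rng.integers(1, p + 1))
            X = rng.normal(size=(n, p))
            X -= X.mean(axis=0)
            y = rng.normal(size=n)
            y -= y.mean()
            assert covsel(X, y, k) == brute_force_covsel(X, y, k)

    def test_n_select_exceeding_p_errors(self):
        with pytest.raises(DataError, match="n_select"):
            covsel(np.ones((4, 2)), np.ones(4), 3)


class TestOrthogonalize:
    def test_self_regression_residual_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(20, 1))
        resid, coeffs = orthogonalize_block(x, x)
        assert np.linalg.norm(resid) < 1e-10
        assert coeffs[0, 0] == pytest.approx(1.0)

    def test_orthogonal_input_unchanged(self):
        sel = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        nxt = np.array([[1.0], [-1.0], [1.0], [-1.0]])
        resid, _ = orthogonalize_block(nxt, sel)
        assert np.allclose(resid, nxt, atol=1e-10)

    def test_hand_computed_least_squares(self):
        sel = np.array([[1.0], [1.0], [-1.0], [-1.0]])
        nxt = np.array([[2.0], [2.0], [0.0], [0.0]])
        resid, coeffs = orthogonalize_block(nxt, sel)
        assert coeffs[0, 0] == pytest.approx(1.0)
        assert np.allclose(resid.ravel(), [1.0, 1.0, 1.0, 1.0])

    def test_empty_selection_is_identity(self):
        nxt = np.arange(6.0).reshape(3, 2)
        resid, coeffs = orthogonalize_block(nxt, np.empty((3, 0)))
        assert np.allclose(resid, nxt)
        assert coeffs.shape == (0, 2)

    def test_row_mismatch_errors(self):
        with pytest.raises(DataError, match="row mismatch"):
            orthogonalize_block(np.ones((4, 2)), np.ones((3, 1)))


class TestEnumeration:
    @pytest.mark.parametrize(
        "n,expected", [(1, 1), (2, 4), (3, 15), (4, 64), (5, 325), (6, 1956)]
    )
    def test_count_is_sum_of_permutations(self, n, expected):
        ids = [f"b{i}" for i in range(n)]
        orders = enumerate_block_orders(ids)
        assert len(orders) == expected
        assert len(set(orders)) == expected

    def test_two_blocks_explicit(self):
        assert enumerate_block_orders(["B", "A"]) == [("A",), ("B",), ("A", "B"), ("B", "A")]

    def test_empty_errors(self):
        with pytest.raises(DataError, match="at least one"):
            enumerate_block_orders([])


def _toy_dataset(block_arrays, seed=0):
    index = pd.Index([f"s{i}" for i in range(len(next(iter(block_arrays.values()))))])
    blocks = [
        AnalyteBlock(
            block_id=name,
            data=pd.DataFrame(arr, index=index, columns=[f"{name}_v{j}" for j in range(arr.shape[1])]),
            stage="autoscaled",
        )
        for name, arr in block_arrays.items()
    ]
    samples = pd.DataFrame({"subject_id": index, "group": "case"}, index=index)
    return MultiBlockDataset(blocks=blocks, samples=samples)


class TestFit:
    def test_redundant_block_contributes_nothing(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(20), np.zeros(20)]
        # first column carries the entire class signal; the rest is noise
        A = np.column_stack([2 * y - 1, rng.normal(size=(40, 2))])
        ds = _toy_dataset({"A": A, "B": A.copy()})
        model = fit_so_covsel_lda(ds, y, ("A", "B"), [1, 1])
        assert model.counts["A"] == 1
        assert model.counts["B"] == 0  # orthogonalized copy has no residual covariance

    def test_planted_analytes_selected_in_every_block(self):
        cfg = SimConfig(
            n_case=100,
            n_control=100,
            block_specs=[("A", 20, 1), ("B", 15, 1), ("C", 10, 1)],
            effect_size=2.0,
            within_subject_repeats=0,
            missing_rate=0.0,
            zero_rate=0.0,
            qc_count=0,
            seed=5,
        )
        ds, truth = generate_multiblock(cfg)
        scaled, _ = preprocess_dataset(ds, normalization="total_ion_sum")
        y = ds.groups().to_numpy()
        model = fit_so_covsel_lda(scaled, list(y), tuple(ds.block_ids), [1, 1, 1])
        for block_id in ds.block_ids:
            assert set(model.selected[block_id]) == truth.informative_ids(block_id)

    def test_zero_count_block_skipped(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(30, 4))
        B = rng.normal(size=(30, 4))
        y = (B[:, 1] > 0).astype(float)
        ds = _toy_dataset({"A": A, "B": B})
        model = fit_so_covsel_lda(ds, y, ("A", "B"), [0, 2])
        single = fit_so_covsel_lda(ds, y, ("B",), [2])
        assert model.selected["A"] == []
        assert model.selected["B"] == single.selected["B"]
        assert np.array_equal(predict_so_covsel(model, ds), predict_so_covsel(single, ds))

    def test_training_predictions_reproduce_confusion(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(50, 6))
        y = (A[:, 0] + 0.5 * rng.normal(size=50) > 0).astype(float)
        ds = _toy_dataset({"A": A})
        model = fit_so_covsel_lda(ds, y, ("A",), [2])
        p1 = predict_so_covsel(model, ds)
        p2 = predict_so_covsel(model, ds)
        assert np.array_equal(p1, p2)

    def test_order_invariance_for_orthogonal_blocks(self):
        """Mutually orthogonal blocks yield identical selections whatever the order."""
        rng = np.random.default_rng(6)
        basis = np.linalg.qr(rng.normal(size=(40, 8)))[0]
        A, B = basis[:, :4] * 3.0, basis[:, 4:] * 3.0
        y = A[:, 0] + B[:, 2] + 0.05 * rng.normal(size=40)
        ds = _toy_dataset({"A": A, "B": B})
        sel = set()
        for order in [("A", "B"), ("B", "A")]:
            model = fit_so_covsel_lda(ds, (y > np.median(y)).astype(float), order, [1, 1])
            sel.add(frozenset(model.selected_ids))
        assert len(sel) == 1


class TestLda:
    def test_midpoint_boundary_with_equal_priors(self):
        Z = np.array([[0.0], [0.0], [2.0], [2.0]])
        labels = ["control", "control", "case", "case"]
        clf = fit_lda(np.r_[Z + [[0.1]], Z - [[0.1]]], labels + labels)
        assert clf.predict(np.array([[0.9]]))[0] == "control"
        assert clf.predict(np.array([[1.1]]))[0] == "case"

    def test_equal_means_assignment_driven_by_priors(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(60, 2))
        labels = ["case"] * 45 + ["control"] * 15
        clf = fit_lda(Z, labels)
        clf.means["control"] = clf.means["case"].copy()
        preds = clf.predict(rng.normal(size=(200, 2)))
        assert (preds == "case").all()

    def test_approaches_bayes_boundary_with_n(self):
        rng = np.random.default_rng(8)
        n = 4000
        Z = np.r_[rng.normal(0, 1, size=(n, 1)), rng.normal(2, 1, size=(n, 1))]
        labels = ["control"] * n + ["case"] * n
        clf = fit_lda(Z, labels)
        grid = np.linspace(0.5, 1.5, 2001)[:, None]
        preds = clf.predict(grid)
        boundary = grid[np.argmax(preds == "case"), 0]
        assert boundary == pytest.approx(1.0, abs=0.1)

    def test_singular_covariance_gets_ridge(self):
        Z = np.array([[0.0, 0.0], [0.1, 0.1], [1.0, 1.0], [1.1, 1.1]])
        clf = fit_lda(Z, ["control", "control", "case", "case"])
        assert clf.ridge > 0
        assert np.isfinite(np.linalg.cond(clf.covariance))


class TestGridSelect:
    def _planted(self, seed=9):
        cfg = SimConfig(
            n_case=60,
            n_control=60,
            block_specs=[("A", 15, 2), ("B", 12, 0)],
            effect_size=2.5,
            within_subject_repeats=0,
            missing_rate=0.0,
            zero_rate=0.0,
            qc_count=0,
            seed=seed,
        )
        ds, truth = generate_multiblock(cfg)
        scaled, _ = preprocess_dataset(ds, normalization="total_ion_sum")
        return scaled, ds.groups().tolist(), ds.subjects().tolist(), truth

    def test_uninformative_block_tends_to_zero(self):
        """CV grid selection concentrates on the informative block; the pure
        noise block usually gets a zero count (CV accuracy is itself noisy, so
        the tendency is asserted over seeds rather than for a single run)."""
        informative, noise = [], []
        for seed in (9, 10, 11, 12, 13):
            scaled, y, subjects, _ = self._planted(seed=seed)
            best, _ = grid_select(scaled, y, subjects, ("A", "B"), [2, 2], folds=4, seed=0)
            informative.append(best[0])
            noise.append(best[1])
        assert all(c >= 1 for c in informative)
        assert sum(c == 0 for c in noise) >= 3
        assert sum(noise) < sum(informative)

    def test_parsimony_tie_break(self):
        scaled, y, subjects, _ = self._planted(seed=10)
        _, report = grid_select(scaled, y, subjects, ("A", "B"), [2, 1], folds=4, seed=0)
        top = report[report["cv_accuracy"] == report["cv_accuracy"].max()]
        chosen, _ = grid_select(scaled, y, subjects, ("A", "B"), [2, 1], folds=4, seed=0)
        assert sum(chosen) == top["total"].min()

    def test_single_point_grid(self):
        scaled, y, subjects, _ = self._planted(seed=11)
        best, report = grid_select(scaled, y, subjects, ("A",), [1], folds=4, seed=0)
        assert best == (1,)
        assert len(report) == 1
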
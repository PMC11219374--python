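"""SO-CovSel-LDA: sequential orthogonalized covariance selection across blocks.

CovSel greedily picks, within one block, the variable with the greatest
squared covariance to the (deflated) class response, deflating data and
response after each pick so redundant variables are never selected twice.
The multi-block extension processes blocks in a given order, orthogonalizing
each block against all previously selected variables before running CovSel
on it, so later blocks can only contribute information the earlier ones did
not.  A linear discriminant classifier (pooled within-class covariance,
training-frequency priors) is fitted on the pooled selections.  All ordered
block combinations can be enumerated (four blocks give 64 models) and the
per-block selection counts chosen by grouped cross-validation with a
parsimony tie-break.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import MultiBlockDataset
from .errors import DataError
from .evaluate import confusion
from .plsda import decode_labels, encode_labels, grouped_stratified_folds

#: covariance below this is treated as exhausted (early stop)
COV_EPS = 1e-12


def covsel(X: np.ndarray, y: np.ndarray, n_select: int) -> list[int]:
    """Greedy covariance selection with deflation.

    At each step picks the column of the deflated ``X`` with maximal squared
    sample covariance to the deflated ``y`` (ties -> lowest index), then
    projects the selected column out of both.  Stops early when the best
    squared covariance drops below :data:`COV_EPS`, so fewer than
    ``n_select`` indices may be returned.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    n, p = X.shape
    if n_select > p:
        raise DataError(f"n_select={n_select} exceeds the {p} available variables")
    selected: list[int] = []
    denom = max(n - 1, 1)
    for _ in range(n_select):
        cov = (X.T @ y) / denom
        cov[selected] = 0.0
        sq = cov**2
        j = int(np.argmax(sq))  # argmax returns the lowest index on ties
        if sq[j] < COV_EPS:
            break
        selected.append(j)
        t = X[:, j].copy()
        tt = t @ t
        if tt < COV_EPS:
            break
        X -= np.outer(t, (t @ X) / tt)
        y = y - t * ((t @ y) / tt)
    return selected


def orthogonalize_block(
    X_next: np.ndarray, X_selected: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Regress each column of ``X_next`` on ``X_selected`` and return
    (residuals, coefficient matrix).

    Uses least squares with pseudo-inverse behavior for rank deficiency.
    With no previously selected variables the residuals equal the input and
    the coefficient matrix has zero rows.
    """
    X_next = np.asarray(X_next, dtype=float)
    X_selected = np.asarray(X_selected, dtype=float)
    if X_selected.ndim == 1:
        X_selected = X_selected[:, None]
    if X_selected.size == 0:
        return X_next.copy(), np.zeros((X_selected.shape[1] if X_selected.ndim == 2 else 0, X_next.shape[1]))
    if X_selected.shape[0] != X_next.shape[0]:
        raise DataError(
            f"row mismatch: {X_selected.shape[0]} selected rows vs {X_next.shape[0]} block rows"
        )
    coeffs, *_ = np.linalg.lstsq(X_selected, X_next, rcond=None)
    residual = X_next - X_selected @ coeffs
    return residual, coeffs


def enumerate_block_orders(block_ids: Sequence[str]) -> list[tuple[str, ...]]:
    """All ordered non-empty sequences of distinct blocks, lexicographic.

    Count is sum over k of P(n, k); four blocks give 4 + 12 + 24 + 24 = 64.
    """
    ids = sorted(set(block_ids))
    if not ids:
        raise DataError("need at least one block id")
    if len(ids) > 6:
        raise DataError(f"at most 6 blocks supported, got {len(ids)}")
    orders: list[tuple[str, ...]] = []
    for k in range(1, len(ids) + 1):
        orders.extend(itertools.permutations(ids, k))
    return orders


@dataclass
class LdaClassifier:
    """Two-class linear discriminant on the pooled selected variables."""

    means: dict[str, np.ndarray]  # class -> mean vector
    covariance: np.ndarray  # pooled within-class covariance (ridge-stabilized if needed)
    priors: dict[str, float]
    ridge: float = 0.0

    def discriminant_scores(self, Z: np.ndarray) -> pd.DataFrame:
        Sinv = np.linalg.inv(self.covariance)
        cols = {}
        for cls in sorted(self.means):
            mu = self.means[cls]
            w = Sinv @ mu
            cols[cls] = Z @ w - 0.5 * mu @ w + np.log(self.priors[cls])
        return pd.DataFrame(cols)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        scores = self.discriminant_scores(Z)
        # tie goes to "case" (positive class), mirroring the PLS-DA boundary rule
        case = scores["case"].to_numpy() >= scores["control"].to_numpy()
        return np.where(case, "case", "control")


def fit_lda(Z: np.ndarray, labels: Sequence, condition_cap: float = 1e10) -> LdaClassifier:
    """Pooled-covariance LDA with automatic ridge when near-singular.

    Ridge lambda = 1e-8 * trace(S)/p is added only if the pooled covariance's
    condition number exceeds ``condition_cap``.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.array([("case" if l in ("case", 1) else "control") for l in labels])
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise DataError("LDA training labels contain a single class")
    n, p = Z.shape
    means, priors = {}, {}
    S = np.zeros((p, p))
    for cls in classes:
        sub = Z[labels == cls]
        means[cls] = sub.mean(axis=0)
        priors[cls] = sub.shape[0] / n
        centered = sub - means[cls]
        S += centered.T @ centered
    S /= max(n - len(classes), 1)
    ridge = 0.0
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > condition_cap:
        ridge = 1e-8 * np.trace(S) / p
        if ridge <= 0:
            ridge = 1e-8
        S = S + ridge * np.eye(p)
    return LdaClassifier(means=means, covariance=S, priors=priors, ridge=ridge)


@dataclass
class SoCovSelModel:
    """Fitted SO-CovSel-LDA model."""

    block_order: tuple[str, ...]
    selected: dict[str, list[str]]  # block -> analyte ids in selection order
    orthogonalization: dict[str, np.ndarray]  # block -> coeffs (n_prev_selected x n_sel_in_block)
    lda: LdaClassifier
    training_subjects: list[str] | None = None

    @property
    def selected_ids(self) -> list[str]:
        return [a for b in self.block_order for a in self.selected[b]]

    @property
    def counts(self) -> dict[str, int]:
        return {b: len(self.selected[b]) for b in self.block_order}

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)


def _selected_matrix(model_order, selected, ortho, dataset) -> np.ndarray:
    """Rebuild the pooled orthogonalized selected-variable matrix for new rows."""
    Z = np.empty((len(dataset.samples), 0))
    for block_id in model_order:
        sel = selected[block_id]
        if not sel:
            continue
        block = dataset[block_id]
        missing = [a for a in sel if a not in block.data.columns]
        if missing:
            raise DataError(f"block {block_id!r} lacks selected analyte(s) {missing}")
        cols = block.data[sel].to_numpy(dtype=float)
        coeffs = ortho[block_id]
        resid = cols - Z @ coeffs if coeffs.size else cols
        Z = np.hstack([Z, resid])
    return Z


def fit_so_covsel_lda(
    dataset_train: MultiBlockDataset,
    labels: Sequence,
    block_order: Sequence[str],
    n_vars_per_block: Sequence[int],
    training_subjects: Sequence[str] | None = None,
) -> SoCovSelModel:
    """Fit one SO-CovSel-LDA model for a given block order and per-block counts.

    For each block in order: orthogonalize it against everything selected so
    far, run CovSel on the residuals, and append the picks.  CovSel's early
    stop permits fewer selections than requested (a redundant block can end
    up contributing nothing).  The LDA is fitted on the pooled
    orthogonalized selections.
    """
    block_order = tuple(block_order)
    if len(block_order) != len(n_vars_per_block):
        raise DataError("n_vars_per_block must align with block_order")
    if sum(n_vars_per_block) < 1:
        raise DataError("at least one variable must be requested across blocks")
    y = encode_labels(labels)
    if len(set(y)) < 2:
        raise DataError("training labels contain a single class")
    yc = y - y.mean()

    n = len(y)
    Z = np.empty((n, 0))
    selected: dict[str, list[str]] = {}
    ortho: dict[str, np.ndarray] = {}
    for block_id, n_sel in zip(block_order, n_vars_per_block):
        block = dataset_train[block_id]
        if n_sel == 0:
            selected[block_id] = []
            ortho[block_id] = np.zeros((Z.shape[1], 0))
            continue
        X = block.data.to_numpy(dtype=float)
        resid, coeffs = orthogonalize_block(X, Z)
        picks = covsel(resid, yc, n_sel)
        ids = [block.data.columns[j] for j in picks]
        selected[block_id] = ids
        ortho[block_id] = coeffs[:, picks] if coeffs.size else np.zeros((0, len(picks)))
        if picks:
            Z = np.hstack([Z, resid[:, picks]])
    if Z.shape[1] == 0:
        raise DataError("CovSel selected no variables in any block (no residual covariance)")
    lda = fit_lda(Z, labels)
    return SoCovSelModel(
        block_order=block_order,
        selected=selected,
        orthogonalization=ortho,
        lda=lda,
        training_subjects=list(training_subjects) if training_subjects is not None else None,
    )


def predict_so_covsel(model: SoCovSelModel, dataset_new: MultiBlockDataset) -> np.ndarray:
    """Classify new (preprocessed-with-the-model's-state) samples."""
    Z = _selected_matrix(model.block_order, model.selected, model.orthogonalization, dataset_new)
    return model.lda.predict(Z)


def grid_select(
    dataset_train: MultiBlockDataset,
    labels: Sequence,
    subject_ids: Sequence[str],
    block_order: Sequence[str],
    grid: Mapping[str, int] | Sequence[int],
    folds: int = 5,
    seed: int = 0,
) -> tuple[tuple[int, ...], pd.DataFrame]:
    """Choose per-block selection counts by grouped stratified CV.

    ``grid`` gives the maximum count per block (0..max each, the all-zero
    vector excluded).  Selection maximizes pooled CV accuracy; ties prefer
    the smallest total variable count, then the lexicographically smallest
    count vector — the parsimony rule favouring the leanest model.
    """
    block_order = tuple(block_order)
    if isinstance(grid, Mapping):
        maxima = [int(grid[b]) for b in block_order]
    else:
        maxima = [int(g) for g in grid]
        if len(maxima) != len(block_order):
            raise DataError("grid must align with block_order")
    if not maxima or max(maxima) < 1:
        raise DataError("grid must allow at least one variable in some block")

    y = encode_labels(labels)
    fold_indices = grouped_stratified_folds(y, subject_ids, folds, seed)
    sample_ids = dataset_train.sample_ids
    true = decode_labels(y)

    candidates = [
        combo
        for combo in itertools.product(*[range(m + 1) for m in maxima])
        if any(combo)
    ]
    rows = []
    best = None  # (neg accuracy, total, combo) for min-comparison
    for combo in candidates:
        predicted = np.empty(len(y), dtype=object)
        for held in fold_indices:
            train_idx = np.setdiff1d(np.arange(len(y)), held)
            sub_train = dataset_train.subset([sample_ids[i] for i in train_idx])
            sub_held = dataset_train.subset([sample_ids[i] for i in held])
            model = fit_so_covsel_lda(sub_train, y[train_idx], block_order, combo)
            predicted[held] = predict_so_covsel(model, sub_held)
        rep = confusion(true, list(predicted), context="CV")
        rows.append(
            {
                **{f"n_{b}": c for b, c in zip(block_order, combo)},
                "total": sum(combo),
                "cv_accuracy": rep.accuracy,
                "cv_sensitivity": rep.sensitivity,
                "cv_specificity": rep.specificity,
            }
        )
        key = (-rep.accuracy, sum(combo), combo)
        if best is None or key < best:
            best = key
    report = pd.DataFrame(rows)
    return tuple(best[2]), report


def run_block_orders(
    dataset_train: MultiBlockDataset,
    labels_train: Sequence,
    dataset_test: MultiBlockDataset | None,
    labels_test: Sequence | None,
    n_vars_per_block: Mapping[str, int] | int,
    subject_ids: Sequence[str] | None = None,
    folds: int = 5,
    seed: int = 0,
    orders: Sequence[Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Fit SO-CovSel-LDA for every enumerated block order.

    Emits one row per order with per-block selected counts, training (and,
    when provided, CV and test) accuracy/sensitivity/specificity, and the
    selected analyte ids — the shape of a 64-model supplementary table.
    """
    if orders is None:
        orders = enumerate_block_orders(dataset_train.block_ids)
    y = encode_labels(labels_train)
    true_train = decode_labels(y)
    rows = []
    for order in orders:
        counts = [
            n_vars_per_block if isinstance(n_vars_per_block, int) else int(n_vars_per_block[b])
            for b in order
        ]
        model = fit_so_covsel_lda(dataset_train, y, order, counts)
        rep_train = confusion(true_train, predict_so_covsel(model, dataset_train), "training")
        row = {
            "order": " > ".join(order),
            **{f"n_{b}": model.counts.get(b, 0) for b in dataset_train.block_ids},
            "selected": ";".join(model.selected_ids),
            "train_accuracy": rep_train.accuracy,
            "train_sensitivity": rep_train.sensitivity,
            "train_specificity": rep_train.specificity,
        }
        if subject_ids is not None:
            predicted = np.empty(len(y), dtype=object)
            sample_ids = dataset_train.sample_ids
            for held in grouped_stratified_folds(y, subject_ids, folds, seed):
                train_idx = np.setdiff1d(np.arange(len(y)), held)
                m = fit_so_covsel_lda(
                    dataset_train.subset([sample_ids[i] for i in train_idx]),
                    y[train_idx],
                    order,
                    counts,
                )
                predicted[held] = predict_so_covsel(
                    m, dataset_train.subset([sample_ids[i] for i in held])
                )
            rep_cv = confusion(true_train, list(predicted), "CV")
            row.update(
                cv_accuracy=rep_cv.accuracy,
                cv_sensitivity=rep_cv.sensitivity,
                cv_specificity=rep_cv.specificity,
            )
        if dataset_test is not None and labels_test is not None:
            rep_test = confusion(
                labels_test, predict_so_covsel(model, dataset_test), "test"
            )
            row.update(
                test_accuracy=rep_test.accuracy,
                test_sensitivity=rep_test.sensitivity,
                test_specificity=rep_test.specificity,
            )
        rows.append(row)
    return pd.DataFrame(rows)
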
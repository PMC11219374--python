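"""Two-class PLS-DA: NIPALS extraction, VIP scores, prediction, CV model selection.

The classifier regresses a centered {0, 1} class dummy (control -> 0,
case -> 1) on the autoscaled feature matrix via sequential NIPALS
latent-variable extraction with deflation.  Predicted responses are mapped
to classes by a 0.5 threshold on the uncentered scale (a tie at exactly 0.5
goes to the positive class, case).  Variable importance in projection (VIP)
is normalized so that the mean squared VIP over analytes is one; VIP > 1
flags influential analytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .evaluate import confusion, ClassificationReport

LABEL_CODES = {"control": 0, "case": 1}


def encode_labels(labels: Sequence) -> np.ndarray:
    """Map case/control labels (or 0/1 ints) to the {0, 1} dummy coding."""
    out = np.empty(len(labels), dtype=float)
    for i, lab in enumerate(labels):
        if lab in LABEL_CODES:
            out[i] = LABEL_CODES[lab]
        elif lab in (0, 1):
            out[i] = float(lab)
        else:
            raise DataError(f"unknown class label {lab!r}; expected case/control or 0/1")
    return out


def decode_labels(codes: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(codes) >= 0.5, "case", "control")


@dataclass
class PlsdaModel:
    """Fitted two-class PLS-DA model."""

    n_lv: int
    weights: pd.DataFrame  # W, analytes x LV
    loadings: pd.DataFrame  # P, analytes x LV
    q: np.ndarray  # response loadings per LV
    scores: pd.DataFrame  # T, training samples x LV
    coefficients: pd.Series  # b such that y_hat = X b + y_mean
    y_mean: float
    vip: pd.Series
    threshold: float = 0.5
    training_subjects: list[str] | None = None

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.weights.index)

    def vip_above(self, cutoff: float = 1.0) -> list[str]:
        """Analytes with VIP strictly greater than ``cutoff`` (VIP>1 convention)."""
        return list(self.vip.index[self.vip > cutoff])


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_lv: int, tol: float = 1e-10, max_iter: int = 500):
    """Sequential PLS1 extraction with deflation of X and y.

    With a single response column the NIPALS inner loop converges in one
    pass (w proportional to X'y); the iteration cap is kept for safety.
    Weight signs are fixed so each weight vector's largest-|entry| is
    positive.
    """
    n, p = X.shape
    Xd, yd = X.copy(), y.copy()
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    T = np.zeros((n, n_lv))
    q = np.zeros(n_lv)
    for a in range(n_lv):
        w = Xd.T @ yd
        norm = np.linalg.norm(w)
        if norm < tol:
            raise DataError(
                f"no residual covariance left at latent variable {a + 1}; "
                f"reduce n_lv below {a + 1}"
            )
        w /= norm
        for _ in range(max_iter):
            t = Xd @ w
            q_a = (yd @ t) / (t @ t)
            w_new = Xd.T @ yd
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = t @ t
        p_a = Xd.T @ t / tt
        q_a = yd @ t / tt
        Xd -= np.outer(t, p_a)
        yd -= t * q_a
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
    return W, P, T, q


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray, a: int) -> np.ndarray:
    """Regression vector for the first ``a`` latent variables: b = W (P'W)^-1 q."""
    Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def fit_plsda(
    X: pd.DataFrame,
    labels: Sequence,
    n_lv: int,
    training_subjects: Sequence[str] | None = None,
) -> PlsdaModel:
    """Fit PLS-DA on an autoscaled training matrix.

    ``labels`` are case/control (or 1/0).  The dummy response is centered
    for fitting; predictions add the training class mix back before
    thresholding at 0.5.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
    y_raw = encode_labels(labels)
    if len(set(y_raw)) < 2:
        raise DataError("training labels contain a single class")
    n, p = X.shape
    if not 1 <= n_lv <= min(n - 1, p):
        raise DataError(f"n_lv={n_lv} out of range; need 1 <= n_lv <= min(n-1, p) = {min(n - 1, p)}")
    y_mean = float(y_raw.mean())
    y = y_raw - y_mean
    W, P, T, q = _nipals_pls1(X.to_numpy(dtype=float), y, n_lv)
    b = _coefficients(W, P, q, n_lv)
    vip = compute_vip(W, T, q)
    lv_names = [f"LV{a + 1}" for a in range(n_lv)]
    return PlsdaModel(
        n_lv=n_lv,
        weights=pd.DataFrame(W, index=X.columns, columns=lv_names),
        loadings=pd.DataFrame(P, index=X.columns, columns=lv_names),
        q=q,
        scores=pd.DataFrame(T, index=X.index, columns=lv_names),
        coefficients=pd.Series(b, index=X.columns),
        y_mean=y_mean,
        vip=pd.Series(vip, index=X.columns, name="VIP"),
        training_subjects=list(training_subjects) if training_subjects is not None else None,
    )


def compute_vip(W: np.ndarray, T: np.ndarray, q: np.ndarray) -> np.ndarray:
    """VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ).

    SSY_a = q_a^2 t_a't_a is the response variance captured by component a.
    The normalization makes the mean squared VIP equal one.
    """
    p, n_lv = W.shape
    ssy = np.array([q[a] ** 2 * (T[:, a] @ T[:, a]) for a in range(n_lv)])
    wnorm2 = (W**2) / np.maximum((W**2).sum(axis=0), 1e-300)
    return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())


def predict_plsda(model: PlsdaModel, X_new: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predict class labels and continuous responses for new (scaled) samples."""
    if not isinstance(X_new, pd.DataFrame):
        X_new = pd.DataFrame(X_new, columns=model.analyte_ids)
    missing = model.coefficients.index.difference(X_new.columns)
    if len(missing):
        raise DataError(f"prediction matrix lacks analyte(s) {list(missing)[:5]}")
    y_hat = X_new[model.coefficients.index].to_numpy() @ model.coefficients.to_numpy() + model.y_mean
    labels = decode_labels((y_hat >= model.threshold).astype(float))
    return labels, y_hat


def grouped_stratified_folds(
    labels: Sequence, subject_ids: Sequence[str], folds: int, seed: int
) -> list[list[int]]:
    """Deterministic grouped stratified k-fold: subjects never split across
    folds; within each class, shuffled subjects are dealt round-robin."""
    labels = np.asarray(labels)
    subject_ids = np.asarray(subject_ids)
    subj_class: dict[str, object] = {}
    for lab, subj in zip(labels, subject_ids):
        prev = subj_class.setdefault(subj, lab)
        if prev != lab:
            raise DataError(f"subject {subj!r} carries both class labels")
    classes = sorted(set(map(str, subj_class.values())))
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for cls in classes:
        members = sorted(s for s, lab in subj_class.items() if str(lab) == cls)
        if len(members) < folds:
            raise DataError(
                f"class {cls!r} has {len(members)} subjects, fewer than {folds} folds"
            )
        rng.shuffle(members)
        for i, subj in enumerate(members):
            fold_of[subj] = i % folds
    out: list[list[int]] = [[] for _ in range(folds)]
    for i, subj in enumerate(subject_ids):
        out[fold_of[subj]].append(i)
    return out


def cv_select_lv(
    X: pd.DataFrame,
    labels: Sequence,
    subject_ids: Sequence[str],
    max_lv: int,
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the latent-variable count by grouped stratified CV.

    Returns the LV count maximizing pooled CV accuracy (ties -> fewest LVs)
    together with a per-LV report (accuracy/sensitivity/specificity in %).
    Coefficients for all 1..max_lv counts are read from a single fit per
    fold, so the search costs one NIPALS run per fold.
    """
    if max_lv < 1:
        raise DataError("max_lv must be >= 1")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(X)
    y_raw = encode_labels(labels)
    fold_indices = grouped_stratified_folds(y_raw, subject_ids, folds, seed)
    n = len(y_raw)
    preds = np.zeros((max_lv, n))
    Xv = X.to_numpy(dtype=float)
    for held in fold_indices:
        train = np.setdiff1d(np.arange(n), held)
        cap = min(max_lv, len(train) - 1, X.shape[1])
        y_mean = y_raw[train].mean()
        W, P, T, q = _nipals_pls1(Xv[train], y_raw[train] - y_mean, cap)
        for a in range(1, max_lv + 1):
            b = _coefficients(W, P, q, min(a, cap))
            preds[a - 1, held] = Xv[held] @ b + y_mean
    rows = []
    true = decode_labels(y_raw)
    for a in range(1, max_lv + 1):
        rep = confusion(true, decode_labels((preds[a - 1] >= 0.5).astype(float)), context="CV")
        rows.append(
            {
                "n_lv": a,
                "cv_accuracy": rep.accuracy,
                "cv_sensitivity": rep.sensitivity,
                "cv_specificity": rep.specificity,
                "cv_balanced_accuracy": rep.balanced_accuracy,
            }
        )
    report = pd.DataFrame(rows).set_index("n_lv")
    best = int(report["cv_accuracy"].idxmax())  # idxmax returns first max -> fewest LVs
    return best, report
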
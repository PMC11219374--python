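"""Confusion matrices, classification metrics, external-test evaluation,
and combination of variable signatures across models.

Case is always the positive class: sensitivity means case recall,
specificity control recall.  Pooled accuracy is the overall fraction
correct; balanced accuracy is the per-class mean.  Rates undefined because a
class is absent surface as ``None`` (not-applicable), never as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, LeakageError

_CONTEXTS = ("training", "CV", "test", "external_test")


def _norm_label(lab) -> str:
    if lab in ("case", "control"):
        return lab
    if lab in (0, 1):
        return "case" if lab == 1 else "control"
    raise DataError(f"unknown class label {lab!r}")


@dataclass
class ClassificationReport:
    """Confusion counts and the derived rates, tagged by evaluation context."""

    tp: int
    fn: int
    tn: int
    fp: int
    context: str = "test"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise DataError("confusion counts must be non-negative")
        if self.context not in _CONTEXTS:
            raise DataError(f"unknown context {self.context!r}; expected one of {_CONTEXTS}")

    @property
    def n_case(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_case + self.n_control

    @property
    def sensitivity(self) -> float | None:
        """Case recall in %, or None when no cases were evaluated."""
        return 100.0 * self.tp / self.n_case if self.n_case else None

    @property
    def specificity(self) -> float | None:
        """Control recall in %, or None when no controls were evaluated."""
        return 100.0 * self.tn / self.n_control if self.n_control else None

    @property
    def accuracy(self) -> float | None:
        """Pooled fraction correct in %."""
        return 100.0 * (self.tp + self.tn) / self.total if self.total else None

    @property
    def balanced_accuracy(self) -> float | None:
        """Per-class mean of sensitivity and specificity, in %."""
        se, sp = self.sensitivity, self.specificity
        if se is None or sp is None:
            return None
        return (se + sp) / 2.0

    def to_dict(self, ndigits: int | None = 2) -> dict:
        def fmt(v):
            if v is None:
                return "NA"
            return round(v, ndigits) if ndigits is not None else v

        return {
            "context": self.context,
            "TP": self.tp,
            "FN": self.fn,
            "TN": self.tn,
            "FP": self.fp,
            "accuracy_pct": fmt(self.accuracy),
            "sensitivity_pct": fmt(self.sensitivity),
            "specificity_pct": fmt(self.specificity),
            "balanced_accuracy_pct": fmt(self.balanced_accuracy),
        }


def confusion(
    true_labels: Sequence, predicted_labels: Sequence, context: str = "test"
) -> ClassificationReport:
    """Tabulate a two-class confusion matrix (case = positive class)."""
    if len(true_labels) != len(predicted_labels):
        raise DataError(
            f"label vectors differ in length ({len(true_labels)} vs {len(predicted_labels)})"
        )
    tp = fn = tn = fp = 0
    for t, p in zip(true_labels, predicted_labels):
        t, p = _norm_label(t), _norm_label(p)
        if t == "case":
            tp, fn = (tp + 1, fn) if p == "case" else (tp, fn + 1)
        else:
            tn, fp = (tn + 1, fp) if p == "control" else (tn, fp + 1)
    return ClassificationReport(tp=tp, fn=fn, tn=tn, fp=fp, context=context)


def external_test(
    model,
    dataset_external,
    labels_external: Sequence,
    context: str = "external_test",
) -> ClassificationReport:
    """Evaluate a fitted model on an external sample set.

    The external subjects must be disjoint from the model's training
    subjects (leakage guard); preprocessing must already have been applied
    via the model's fitted state, never refit.  Works for any model exposing
    a prediction route used by this package (PLS-DA or SO-CovSel-LDA).
    """
    train_subjects = set(getattr(model, "training_subjects", None) or [])
    if train_subjects and hasattr(dataset_external, "subjects"):
        overlap = train_subjects & set(dataset_external.subjects().dropna())
        if overlap:
            raise LeakageError(
                f"external set shares {len(overlap)} subject(s) with training, e.g. "
                f"{sorted(overlap)[:3]}"
            )
    predicted = _predict_any(model, dataset_external)
    return confusion(labels_external, predicted, context=context)


def _predict_any(model, data):
    # local imports to avoid circular module dependencies
    from .plsda import PlsdaModel, predict_plsda
    from .socovsel import SoCovSelModel, predict_so_covsel

    if isinstance(model, PlsdaModel):
        matrix = data
        if hasattr(data, "blocks"):
            from .fusion import low_level_fuse

            matrix, _ = low_level_fuse(data, weights="none")
        return predict_plsda(model, matrix)[0]
    if isinstance(model, SoCovSelModel):
        return predict_so_covsel(model, data)
    raise DataError(f"cannot predict with model of type {type(model).__name__}")


def signature_union(
    vip_analytes: Sequence[str], socovsel_analytes: Sequence[str]
) -> pd.DataFrame:
    """Combine the VIP>1 and SO-CovSel analyte signatures.

    Returns one row per analyte in the union, tagged ``vip_only`` /
    ``socovsel_only`` / ``both``, sorted by tag (shared analytes first)
    then id.  The union cardinality is ``len(result)``.
    """
    vip, soc = set(vip_analytes), set(socovsel_analytes)
    rows = []
    for analyte in sorted(vip | soc):
        if analyte in vip and analyte in soc:
            tag = "both"
        elif analyte in vip:
            tag = "vip_only"
        else:
            tag = "socovsel_only"
        rows.append({"analyte": analyte, "source": tag})
    out = pd.DataFrame(rows, columns=["analyte", "source"])
    order = {"both": 0, "vip_only": 1, "socovsel_only": 2}
    return out.sort_values(
        ["source", "analyte"], key=lambda s: s.map(order) if s.name == "source" else s
    ).reset_index(drop=True)
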
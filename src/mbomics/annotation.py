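"""Annotation-quality summaries and diagnosis-severity labeling.

Utilities around the modelling core: summarize MS/MS annotation confidence
for a block's analytes, and apply a registry-style severity rule to a
subject's set of diagnosis codes.
"""

from __future__ import annotations

from typing import Collection, Iterable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError


def annotation_quality_summary(
    analyte_meta: pd.DataFrame,
    score_threshold: float = 800.0,
    ccs_threshold: float = 1.0,
    score_col: str = "ms2_score",
    mass_error_col: str = "mass_error_ppm",
    ccs_col: str = "ccs_error_pct",
) -> dict:
    """Median annotation scores and threshold fractions for one analyte table.

    Fractions use strict inequalities: scores strictly *higher than*
    ``score_threshold`` and CCS errors strictly *lower than*
    ``ccs_threshold`` count.  Columns that are absent yield None entries.
    """
    if score_col not in analyte_meta.columns:
        raise DataError(f"analyte metadata lacks a {score_col!r} column")
    scores = pd.to_numeric(analyte_meta[score_col], errors="coerce").dropna()
    if scores.empty:
        raise DataError("no analyte carries an annotation score")
    out = {
        "n_scored": int(scores.size),
        "median_score": float(scores.median()),
        "fraction_score_above": float((scores > score_threshold).mean()),
        "median_mass_error_ppm": None,
        "median_ccs_error_pct": None,
        "fraction_ccs_below": None,
    }
    if mass_error_col in analyte_meta.columns:
        me = pd.to_numeric(analyte_meta[mass_error_col], errors="coerce").dropna()
        if me.size:
            out["median_mass_error_ppm"] = float(me.median())
    if ccs_col in analyte_meta.columns:
        ccs = pd.to_numeric(analyte_meta[ccs_col], errors="coerce").dropna()
        if ccs.size:
            out["median_ccs_error_pct"] = float(ccs.median())
            out["fraction_ccs_below"] = float((ccs < ccs_threshold).mean())
    return out


def classify_severity(
    diagnosis_codes: Iterable[str],
    severe_set: Collection[str],
    nonsevere_set: Collection[str],
) -> str:
    """Severity label for one subject's diagnosis codes.

    ``severe`` if any code is in the severe set; ``non-severe`` if any code
    is in the non-severe set and none is severe; ``not_classified``
    otherwise.  The two code sets must be disjoint.
    """
    severe_set, nonsevere_set = set(severe_set), set(nonsevere_set)
    overlap = severe_set & nonsevere_set
    if overlap:
        raise ConfigurationError(
            f"severe_set and nonsevere_set overlap on {sorted(overlap)[:5]}"
        )
    codes = set(diagnosis_codes)
    if codes & severe_set:
        return "severe"
    if codes & nonsevere_set:
        return "non-severe"
    return "not_classified"


def classify_severity_table(
    subject_codes: pd.Series | dict,
    severe_set: Collection[str],
    nonsevere_set: Collection[str],
) -> pd.Series:
    """Vectorized severity labeling: subject -> label."""
    items = subject_codes.items() if hasattr(subject_codes, "items") else subject_codes
    return pd.Series(
        {subj: classify_severity(codes, severe_set, nonsevere_set) for subj, codes in items},
        name="severity",
    )
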
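"""Per-block preprocessing: normalization, 1/5-minimum imputation, log10, autoscaling.

The chain runs in a fixed order — normalize -> impute -> log10 -> autoscale —
enforced through the block's ``stage`` tag; applying a step out of order
raises :class:`~mbomics.errors.PipelineOrderError`.  Every fitted statistic
(replacement values, scaling mean/SD) is recorded in a
:class:`PreprocessState` so held-out samples can be transformed with
:func:`apply_state` without refitting (no train/test leakage).  QC rows are
excluded from fitted statistics by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import GROUP_QC, AnalyteBlock, MultiBlockDataset, stage_index
from .errors import DataError, PipelineOrderError

NORMALIZATIONS = ("total_ion_sum", "internal_standard", "none")


def _require_stage(block: AnalyteBlock, allowed: tuple[str, ...], op: str) -> None:
    if block.stage not in allowed:
        raise PipelineOrderError(
            f"{op} expects a block at stage {allowed} but block "
            f"{block.block_id!r} is at stage {block.stage!r} "
            "(order is normalize -> impute -> log10 -> autoscale)"
        )


@dataclass
class PreprocessState:
    """Fitted preprocessing parameters for one block.

    Only the components that were fitted are set; :func:`apply_state`
    replays exactly those on new samples.
    """

    block_id: str
    normalization: str = "none"
    standard_map: dict[str, str] | None = None
    replacement: pd.Series | None = None  # per-analyte value substituted for missing/zero
    log10: bool = False
    center: pd.Series | None = None  # per-analyte scaling mean
    scale: pd.Series | None = None  # per-analyte scaling SD (n-1 denominator)
    fitted_on: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "block_id": self.block_id,
            "normalization": self.normalization,
            "standard_map": self.standard_map,
            "replacement": None if self.replacement is None else self.replacement.to_dict(),
            "log10": self.log10,
            "center": None if self.center is None else self.center.to_dict(),
            "scale": None if self.scale is None else self.scale.to_dict(),
            "fitted_on": list(self.fitted_on),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PreprocessState":
        payload = json.loads(Path(path).read_text())
        for key in ("replacement", "center", "scale"):
            if payload[key] is not None:
                payload[key] = pd.Series(payload[key])
        return cls(**payload)


# ---------------------------------------------------------------------------
# normalization


def normalize_total_ion_sum(block: AnalyteBlock) -> AnalyteBlock:
    """Divide each sample row by its sum of observed intensities.

    Missing entries are untouched, so a fully observed row sums to one.
    Raises if any row has no observed positive signal.
    """
    _require_stage(block, ("raw",), "normalize_total_ion_sum")
    totals = block.data.sum(axis=1, skipna=True)
    bad = totals <= 0
    if bad.any():
        raise DataError(
            f"block {block.block_id!r}: sample(s) {list(block.data.index[bad])} have "
            "zero or all-missing total ion signal"
        )
    return block.with_data(block.data.div(totals, axis=0), stage="normalized")


def normalize_internal_standard(
    block: AnalyteBlock, standard_map: Mapping[str, str]
) -> AnalyteBlock:
    """Divide each analyte by its mapped internal standard in the same sample.

    Standard columns are dropped from the output.  Every non-standard analyte
    must be mapped and every standard intensity must be positive.
    """
    _require_stage(block, ("raw",), "normalize_internal_standard")
    standards = sorted(set(standard_map.values()))
    for std in standards:
        if std not in block.data.columns:
            raise DataError(f"block {block.block_id!r}: internal standard {std!r} absent")
        col = block.data[std]
        bad = ~(col > 0)
        if bad.any():
            raise DataError(
                f"block {block.block_id!r}: standard {std!r} non-positive or missing in "
                f"sample(s) {list(block.data.index[bad])[:5]}"
            )
    targets = [c for c in block.data.columns if c not in standards]
    unmapped = [c for c in targets if c not in standard_map]
    if unmapped:
        raise DataError(
            f"block {block.block_id!r}: analyte(s) {unmapped[:5]} have no internal standard mapping"
        )
    out = pd.DataFrame(
        {c: block.data[c] / block.data[standard_map[c]] for c in targets},
        index=block.data.index,
    )
    return block.with_data(out, stage="normalized")


def skip_normalization(block: AnalyteBlock) -> AnalyteBlock:
    """Mark a raw block as normalized without altering values (tag ``none``)."""
    _require_stage(block, ("raw",), "skip_normalization")
    return block.with_data(block.data, stage="normalized")


# ---------------------------------------------------------------------------
# imputation, log, autoscale


def impute_min_fraction(
    block: AnalyteBlock,
    fraction: float = 0.2,
    fit_rows: Sequence[str] | None = None,
) -> tuple[AnalyteBlock, PreprocessState]:
    """Replace missing values and exact zeros by ``fraction`` x the analyte's
    minimum observed positive intensity.

    The minimum is computed over ``fit_rows`` (default: all rows); the
    replacement values are recorded in the returned state.  Analytes with no
    positive observation are reported in one error.
    """
    _require_stage(block, ("raw", "normalized"), "impute_min_fraction")
    if fraction <= 0:
        raise DataError(f"fraction must be positive, got {fraction}")
    ref = block.data if fit_rows is None else block.data.loc[list(fit_rows)]
    positive = ref.where(ref > 0)
    minima = positive.min(axis=0, skipna=True)
    dead = minima.isna() | (minima <= 0)
    if dead.any():
        raise DataError(
            f"block {block.block_id!r}: analyte(s) with no positive observation: "
            f"{list(minima.index[dead])}"
        )
    replacement = fraction * minima
    state = PreprocessState(
        block_id=block.block_id,
        normalization="none",
        replacement=replacement,
        fitted_on=list(ref.index),
    )
    out = _replace_missing_zero(block.data, replacement)
    return block.with_data(out, stage="imputed"), state


def _replace_missing_zero(data: pd.DataFrame, replacement: pd.Series) -> pd.DataFrame:
    needs = data.isna() | (data == 0)
    return data.mask(needs, replacement, axis=1)


def log_transform(block: AnalyteBlock) -> AnalyteBlock:
    """Elementwise log base 10; all values must be strictly positive."""
    _require_stage(block, ("imputed",), "log_transform")
    values = block.data.to_numpy()
    if np.isnan(values).any() or (values <= 0).any():
        raise DataError(
            f"block {block.block_id!r}: non-positive or missing values remain; "
            "run impute_min_fraction first"
        )
    return block.with_data(np.log10(block.data), stage="log10")


def autoscale(
    block: AnalyteBlock,
    reference_rows: Sequence[str] | None = None,
) -> tuple[AnalyteBlock, PreprocessState]:
    """Center and scale each analyte to mean 0 / SD 1 over ``reference_rows``.

    SD uses the n-1 denominator (chemometrics convention).  The fitted mean
    and SD go into the returned state for reuse on held-out samples.
    """
    _require_stage(block, ("log10",), "autoscale")
    ref = block.data if reference_rows is None else block.data.loc[list(reference_rows)]
    if ref.shape[0] < 2:
        raise DataError(f"block {block.block_id!r}: need >= 2 reference rows to autoscale")
    center = ref.mean(axis=0)
    scale = ref.std(axis=0, ddof=1)
    dead = ~(scale > 0)
    if dead.any():
        raise DataError(
            f"block {block.block_id!r}: zero-variance analyte(s) over reference rows: "
            f"{list(scale.index[dead])}"
        )
    state = PreprocessState(
        block_id=block.block_id,
        center=center,
        scale=scale,
        fitted_on=list(ref.index),
    )
    out = (block.data - center) / scale
    return block.with_data(out, stage="autoscaled"), state


# ---------------------------------------------------------------------------
# fitted-state application and the full per-block chain


def apply_state(block: AnalyteBlock, state: PreprocessState) -> AnalyteBlock:
    """Replay a fitted preprocessing state on new samples without refitting.

    Runs, in order, exactly the components present in the state:
    row-wise normalization (which needs no fitted parameters), recorded
    replacement values, log10, recorded center/scale.
    """
    out = block
    if out.stage == "raw":
        if state.normalization == "total_ion_sum":
            out = normalize_total_ion_sum(out)
        elif state.normalization == "internal_standard":
            if state.standard_map is None:
                raise DataError(f"state for block {state.block_id!r} lacks its standard_map")
            out = normalize_internal_standard(out, state.standard_map)
        elif state.replacement is not None or state.center is not None:
            out = skip_normalization(out)
    if state.replacement is not None:
        _require_stage(out, ("raw", "normalized"), "apply_state(replacement)")
        missing = out.data.columns.difference(state.replacement.index)
        if len(missing):
            raise DataError(
                f"state for block {state.block_id!r} lacks replacement values for "
                f"analyte(s) {list(missing)[:5]}"
            )
        out = out.with_data(
            _replace_missing_zero(out.data, state.replacement.loc[out.data.columns]),
            stage="imputed",
        )
    if state.log10:
        out = log_transform(out)
    if state.center is not None or state.scale is not None:
        if state.center is None or state.scale is None:
            raise DataError(f"state for block {state.block_id!r} has only one of center/scale")
        missing = out.data.columns.difference(state.center.index)
        if len(missing):
            raise DataError(
                f"state for block {state.block_id!r} lacks scaling for analyte(s) "
                f"{list(missing)[:5]}"
            )
        data = (out.data - state.center.loc[out.data.columns]) / state.scale.loc[out.data.columns]
        out = out.with_data(data, stage="autoscaled")
    return out


def preprocess_block(
    block: AnalyteBlock,
    normalization: str = "total_ion_sum",
    standard_map: Mapping[str, str] | None = None,
    fit_rows: Sequence[str] | None = None,
    impute_fraction: float = 0.2,
) -> tuple[AnalyteBlock, PreprocessState]:
    """Run the full chain on one block and return the merged fitted state.

    ``fit_rows`` restricts every fitted statistic (imputation minima,
    scaling mean/SD) to those samples; the transform itself is applied to
    all rows of the block.
    """
    if normalization not in NORMALIZATIONS:
        raise DataError(f"unknown normalization {normalization!r}; expected one of {NORMALIZATIONS}")
    if normalization == "total_ion_sum":
        out = normalize_total_ion_sum(block)
    elif normalization == "internal_standard":
        if standard_map is None:
            raise DataError("internal_standard normalization requires a standard_map")
        out = normalize_internal_standard(block, standard_map)
    else:
        out = skip_normalization(block)
    out, impute_state = impute_min_fraction(out, fraction=impute_fraction, fit_rows=fit_rows)
    out = log_transform(out)
    out, scale_state = autoscale(out, reference_rows=fit_rows)
    state = PreprocessState(
        block_id=block.block_id,
        normalization=normalization,
        standard_map=dict(standard_map) if standard_map else None,
        replacement=impute_state.replacement,
        log10=True,
        center=scale_state.center,
        scale=scale_state.scale,
        fitted_on=list(impute_state.fitted_on),
    )
    return out, state


def preprocess_dataset(
    dataset: MultiBlockDataset,
    normalization: Mapping[str, str] | str = "total_ion_sum",
    standard_maps: Mapping[str, Mapping[str, str]] | None = None,
    fit_rows: Sequence[str] | None = None,
    impute_fraction: float = 0.2,
    include_qc: bool = False,
) -> tuple[MultiBlockDataset, dict[str, PreprocessState]]:
    """Preprocess every block of a dataset.

    ``normalization`` is either one tag for all blocks or a per-block-id
    mapping.  Fitted statistics use ``fit_rows`` when given, otherwise all
    non-QC samples (QC rows are excluded from fitting unless
    ``include_qc``); the transform is applied to every row.
    """
    if fit_rows is None:
        fit_rows = dataset.sample_ids if include_qc else dataset.non_qc_ids
    blocks, states = [], {}
    for block in dataset.blocks:
        tag = normalization if isinstance(normalization, str) else normalization[block.block_id]
        smap = None
        if standard_maps is not None:
            smap = standard_maps.get(block.block_id) or None
        out, state = preprocess_block(
            block,
            normalization=tag,
            standard_map=smap,
            fit_rows=list(fit_rows),
            impute_fraction=impute_fraction,
        )
        blocks.append(out)
        states[block.block_id] = state
    return dataset.with_blocks(blocks), states


def apply_states(
    dataset: MultiBlockDataset, states: Mapping[str, PreprocessState]
) -> MultiBlockDataset:
    """Replay per-block fitted states on a (raw) dataset."""
    blocks = []
    for block in dataset.blocks:
        if block.block_id not in states:
            raise DataError(f"no preprocessing state for block {block.block_id!r}")
        blocks.append(apply_state(block, states[block.block_id]))
    return dataset.with_blocks(blocks)
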
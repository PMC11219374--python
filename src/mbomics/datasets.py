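"""Core containers: analyte blocks and sample-aligned multi-block datasets.

An :class:`AnalyteBlock` is one feature table from a single analytical
modality/polarity (e.g. lipidomics ESI+): a samples x analytes matrix of
non-negative intensities with NaN marking missing values.  A
:class:`MultiBlockDataset` bundles several sample-aligned blocks with shared
sample metadata (sample_id, subject_id, group), the object every pipeline
stage consumes.

Blocks carry a preprocessing ``stage`` tag so that the fixed order
normalize -> impute -> log10 -> autoscale can be enforced at runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

GROUP_CASE = "case"
GROUP_CONTROL = "control"
GROUP_QC = "QC"

#: preprocessing stages in their mandatory order
STAGES = ("raw", "normalized", "imputed", "log10", "autoscaled")

_SAMPLE_COLUMNS = ("sample_id", "subject_id", "group")


def stage_index(stage: str) -> int:
    try:
        return STAGES.index(stage)
    except ValueError:
        raise DataError(f"unknown preprocessing stage {stage!r}; expected one of {STAGES}") from None


@dataclass
class AnalyteBlock:
    """One modality/polarity feature table (samples x analytes).

    Parameters
    ----------
    block_id:
        Identifier such as ``"metabolomics_pos"``.
    data:
        DataFrame indexed by sample_id with one float column per analyte;
        NaN marks a missing intensity.
    analyte_meta:
        Optional per-analyte metadata (name, database id, class, annotation
        score, mass error...), indexed by analyte id.
    stage:
        Preprocessing stage tag, one of :data:`STAGES`.
    """

    block_id: str
    data: pd.DataFrame
    analyte_meta: pd.DataFrame | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data = self.data.astype(float)
        stage_index(self.stage)  # validate tag
        cols = self.data.columns
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise DataError(f"block {self.block_id!r}: duplicate analyte ids {dupes}")
        if self.data.index.duplicated().any():
            dupes = sorted(set(self.data.index[self.data.index.duplicated()]))
            raise DataError(f"block {self.block_id!r}: duplicate sample ids {dupes}")
        if self.stage == "raw":
            values = self.data.to_numpy()
            neg = np.nan_to_num(values, nan=0.0) < 0
            if neg.any():
                i, j = np.argwhere(neg)[0]
                raise DataError(
                    f"block {self.block_id!r}: negative intensity at sample "
                    f"{self.data.index[i]!r}, analyte {cols[j]!r}"
                )
        if self.analyte_meta is not None and not self.analyte_meta.index.equals(cols):
            missing = cols.difference(self.analyte_meta.index)
            if len(missing):
                raise DataError(
                    f"block {self.block_id!r}: analyte_meta lacks entries for {list(missing)[:5]}"
                )
            self.analyte_meta = self.analyte_meta.loc[cols]

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: pd.DataFrame, stage: str | None = None) -> "AnalyteBlock":
        """Copy of this block with new values (and optionally a new stage tag)."""
        meta = self.analyte_meta
        if meta is not None:
            meta = meta.loc[meta.index.intersection(data.columns)].reindex(data.columns)
        return AnalyteBlock(
            block_id=self.block_id,
            data=data,
            analyte_meta=meta,
            stage=self.stage if stage is None else stage,
        )

    def subset(self, sample_ids: Sequence[str]) -> "AnalyteBlock":
        return replace(self, data=self.data.loc[list(sample_ids)])


@dataclass
class MultiBlockDataset:
    """Ordered, sample-aligned analyte blocks plus shared sample metadata.

    ``samples`` is indexed by sample_id with columns ``subject_id`` and
    ``group`` (``case``/``control``/``QC``); every block's rows must match
    that index exactly.
    """

    blocks: list[AnalyteBlock]
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.blocks:
            raise DataError("dataset needs at least one block")
        ids = [b.block_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise DataError(f"duplicate block ids: {ids}")
        for col in ("subject_id", "group"):
            if col not in self.samples.columns:
                raise DataError(f"samples table lacks required column {col!r}")
        if self.samples.index.duplicated().any():
            raise DataError("samples table has duplicate sample ids")
        non_qc = self.samples["group"] != GROUP_QC
        if self.samples.loc[non_qc, "subject_id"].isna().any():
            raise DataError("non-QC samples must all carry a subject_id")
        for b in self.blocks:
            if not b.data.index.equals(self.samples.index):
                raise DataError(
                    f"block {b.block_id!r} is not sample-aligned with the shared sample index"
                )

    @property
    def block_ids(self) -> list[str]:
        return [b.block_id for b in self.blocks]

    def block(self, block_id: str) -> AnalyteBlock:
        for b in self.blocks:
            if b.block_id == block_id:
                return b
        raise KeyError(block_id)

    def __getitem__(self, block_id: str) -> AnalyteBlock:
        return self.block(block_id)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def non_qc_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] != GROUP_QC])

    @property
    def qc_ids(self) -> list[str]:
        return list(self.samples.index[self.samples["group"] == GROUP_QC])

    def groups(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        s = self.samples["group"]
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def subjects(self, sample_ids: Sequence[str] | None = None) -> pd.Series:
        s = self.samples["subject_id"]
        return s if sample_ids is None else s.loc[list(sample_ids)]

    def subset(self, sample_ids: Sequence[str]) -> "MultiBlockDataset":
        sample_ids = list(sample_ids)
        return MultiBlockDataset(
            blocks=[b.subset(sample_ids) for b in self.blocks],
            samples=self.samples.loc[sample_ids],
        )

    def with_blocks(self, blocks: list[AnalyteBlock]) -> "MultiBlockDataset":
        return MultiBlockDataset(blocks=blocks, samples=self.samples)

    def map_blocks(self, fn) -> "MultiBlockDataset":
        return self.with_blocks([fn(b) for b in self.blocks])


# ---------------------------------------------------------------------------
# readers / writers


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_feature_table(path: str | Path, block_id: str, stage: str = "raw") -> tuple[AnalyteBlock, pd.DataFrame]:
    """Read one block CSV/TSV: columns sample_id, subject_id, group, then analytes.

    Empty cells are missing values.  Returns the block together with its
    sample metadata table (indexed by sample_id).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_delimiter_for(path), dtype=str)
    for col in _SAMPLE_COLUMNS:
        if col not in raw.columns:
            raise DataError(f"{path.name}: required column {col!r} absent")
    analyte_cols = [c for c in raw.columns if c not in _SAMPLE_COLUMNS]
    seen: set[str] = set()
    for c in analyte_cols:
        base = c.split(".")[0] if c.split(".")[-1].isdigit() else c
        if base in seen:
            raise DataError(f"{path.name}: duplicate analyte column {base!r}")
        seen.add(base)
    if raw["sample_id"].duplicated().any():
        dupes = sorted(set(raw.loc[raw["sample_id"].duplicated(), "sample_id"]))
        raise DataError(f"{path.name}: duplicate sample ids {dupes}")
    samples = raw[list(_SAMPLE_COLUMNS)].set_index("sample_id")
    matrix = raw[analyte_cols].copy()
    for col in analyte_cols:
        converted = pd.to_numeric(matrix[col], errors="coerce")
        bad = converted.isna() & matrix[col].notna() & (matrix[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{path.name}: non-numeric intensity {matrix[col].iloc[row]!r} "
                f"at row {row}, column {col!r}"
            )
        matrix[col] = converted
    matrix.index = samples.index
    block = AnalyteBlock(block_id=block_id, data=matrix, stage=stage)
    return block, samples


def write_feature_table(block: AnalyteBlock, samples: pd.DataFrame, path: str | Path) -> None:
    """Write one block plus sample metadata as a CSV/TSV feature table."""
    path = Path(path)
    out = samples.loc[block.data.index, ["subject_id", "group"]].copy()
    out.insert(0, "sample_id", block.data.index)
    out = pd.concat([out.reset_index(drop=True), block.data.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=_delimiter_for(path), index=False)


def write_dataset(dataset: MultiBlockDataset, directory: str | Path) -> dict[str, Path]:
    """Write one CSV per block plus a samples CSV; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    samples_path = directory / "samples.csv"
    out = dataset.samples.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(samples_path, index=False)
    paths["samples"] = samples_path
    for block in dataset.blocks:
        p = directory / f"{block.block_id}.csv"
        write_feature_table(block, dataset.samples, p)
        paths[block.block_id] = p
    return paths


def read_dataset(directory: str | Path, block_ids: Iterable[str]) -> MultiBlockDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    directory = Path(directory)
    blocks = []
    samples = None
    for block_id in block_ids:
        block, block_samples = read_feature_table(directory / f"{block_id}.csv", block_id)
        if samples is None:
            samples = block_samples
        blocks.append(block)
    assert samples is not None
    return MultiBlockDataset(blocks=blocks, samples=samples)


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
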
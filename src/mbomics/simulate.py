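"""Synthetic multi-block case/control generator with known ground truth.

Emulates a two-class untargeted LC-MS study in which the same plasma samples
are profiled in four blocks (lipidomics ESI+/ESI-, metabolomics ESI+/ESI-).
Log10 intensities are Gaussian; a small configured set of informative
analytes is shifted up or down in cases; a few subjects contribute two
samples that share a subject-level random effect; pooled-QC samples are
near-average mixtures of study samples.  Everything is deterministic given
the seed, so every downstream stage can be tested against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import GROUP_CASE, GROUP_CONTROL, GROUP_QC, AnalyteBlock, MultiBlockDataset
from .errors import ConfigurationError

#: block widths of the study design this generator emulates
DEFAULT_BLOCK_SPECS: tuple[tuple[str, int, int], ...] = (
    ("lipidomics_pos", 307, 3),
    ("lipidomics_neg", 79, 3),
    ("metabolomics_pos", 74, 3),
    ("metabolomics_neg", 39, 3),
)


@dataclass
class SimConfig:
    """Study-design parameters for the generator.

    ``block_specs`` entries are ``(block_id, n_analytes, n_informative)``.
    ``effect_size`` is the standardized mean shift (in units of
    ``base_log_sd``) applied to informative analytes in cases.
    ``within_subject_repeats`` control subjects each contribute a second
    sample correlated through a shared subject effect (intraclass
    correlation ``icc``).  ``n_internal_standards`` maps a block id to a
    number of spiked internal-standard analytes (constant true concentration,
    small multiplicative noise), occupying that block's first columns.
    """

    n_case: int = 157
    n_control: int = 162
    block_specs: Sequence[tuple[str, int, int]] = DEFAULT_BLOCK_SPECS
    effect_size: float = 1.5
    within_subject_repeats: int = 11
    missing_rate: float = 0.02
    zero_rate: float = 0.01
    qc_count: int = 10
    base_log_mean: float = 5.0
    base_log_sd: float = 0.5
    icc: float = 0.5
    n_internal_standards: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "within_subject_repeats", "qc_count"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_case + self.n_control < 1:
            raise ConfigurationError("n_case + n_control must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if not 0 <= self.zero_rate < 1:
            raise ConfigurationError(f"zero_rate must be in [0, 1), got {self.zero_rate}")
        if not 0 <= self.icc <= 1:
            raise ConfigurationError(f"icc must be in [0, 1], got {self.icc}")
        if self.base_log_sd <= 0:
            raise ConfigurationError(f"base_log_sd must be positive, got {self.base_log_sd}")
        ids = [spec[0] for spec in self.block_specs]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"block_specs: block ids not unique: {ids}")
        if not ids:
            raise ConfigurationError("block_specs must list at least one block")
        for block_id, n_analytes, n_informative in self.block_specs:
            if n_analytes < 1:
                raise ConfigurationError(f"block_specs[{block_id}]: n_analytes must be >= 1")
            n_is = self.n_internal_standards.get(block_id, 0)
            if n_informative < 0 or n_informative + n_is > n_analytes:
                raise ConfigurationError(
                    f"block_specs[{block_id}]: n_informative ({n_informative}) plus internal "
                    f"standards ({n_is}) must fit within n_analytes ({n_analytes})"
                )
        if self.within_subject_repeats > self.n_control:
            raise ConfigurationError(
                "within_subject_repeats cannot exceed n_control "
                f"({self.within_subject_repeats} > {self.n_control})"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "block_specs" in d:
            d["block_specs"] = [tuple(spec) for spec in d["block_specs"]]
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Planted truth: informative analytes with their direction, subject map,
    and internal-standard maps per block."""

    informative: dict[str, dict[str, int]]  # block_id -> {analyte_id: +1 (up in case) / -1}
    subject_map: dict[str, str]  # sample_id -> subject_id
    standard_maps: dict[str, dict[str, str]]  # block_id -> {analyte_id: standard_id}

    def informative_ids(self, block_id: str | None = None) -> set[str]:
        if block_id is not None:
            return set(self.informative.get(block_id, {}))
        return {a for block in self.informative.values() for a in block}


def generate_multiblock(config: SimConfig) -> tuple[MultiBlockDataset, GroundTruth]:
    """Draw one synthetic multi-block dataset.

    Intensities are ``10**(subject effect + residual + case shift)`` around
    ``base_log_mean``; QC rows are per-analyte means of a random sample
    subset plus small noise; missingness and exact zeros are injected last
    (QC rows exempt).  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_case, n_control = config.n_case, config.n_control
    case_subjects = [f"CASE{i:04d}" for i in range(n_case)]
    control_subjects = [f"CTRL{i:04d}" for i in range(n_control)]
    subjects = case_subjects + control_subjects
    groups = [GROUP_CASE] * n_case + [GROUP_CONTROL] * n_control

    # control subjects contributing a second sample (study: repeat mothers)
    repeat_subjects = list(
        rng.choice(control_subjects, size=config.within_subject_repeats, replace=False)
    ) if config.within_subject_repeats else []

    sample_subjects = list(subjects) + list(repeat_subjects)
    sample_groups = list(groups) + [GROUP_CONTROL] * len(repeat_subjects)
    n_study = len(sample_subjects)
    sample_ids = [f"S{i + 1:04d}" for i in range(n_study)]

    sd = config.base_log_sd
    subj_sd = np.sqrt(config.icc) * sd
    resid_sd = np.sqrt(1.0 - config.icc) * sd
    subj_index = {s: i for i, s in enumerate(subjects)}
    sample_rows = np.array([subj_index[s] for s in sample_subjects])

    informative: dict[str, dict[str, int]] = {}
    standard_maps: dict[str, dict[str, str]] = {}
    blocks: list[AnalyteBlock] = []
    case_mask = np.array([g == GROUP_CASE for g in sample_groups])

    for block_id, n_analytes, n_informative in config.block_specs:
        n_is = config.n_internal_standards.get(block_id, 0)
        is_ids = [f"{block_id}_IS{i + 1}" for i in range(n_is)]
        analyte_ids = is_ids + [f"{block_id}_A{i + 1:04d}" for i in range(n_analytes - n_is)]

        # per-analyte subject effects: repeat samples of one subject share a row,
        # giving intraclass correlation `icc` per analyte between repeats
        subject_effects = rng.normal(0.0, subj_sd, size=(len(subjects), n_analytes))
        log_values = (
            config.base_log_mean
            + subject_effects[sample_rows]
            + rng.normal(0.0, resid_sd, size=(n_study, n_analytes))
        )

        # internal standards: constant true level, small multiplicative noise,
        # shared per-sample injection factor is deliberately absent (spiked post-extraction)
        for j in range(n_is):
            log_values[:, j] = config.base_log_mean + rng.normal(0.0, 0.05, size=n_study)

        candidates = list(range(n_is, n_analytes))
        chosen = sorted(rng.choice(candidates, size=n_informative, replace=False)) if n_informative else []
        directions = rng.choice([-1, 1], size=len(chosen))
        info: dict[str, int] = {}
        for j, direction in zip(chosen, directions):
            log_values[case_mask, j] += direction * config.effect_size * sd
            info[analyte_ids[j]] = int(direction)
        informative[block_id] = info

        if n_is:
            # map every non-standard analyte to a standard, round-robin by class
            standard_maps[block_id] = {
                analyte_ids[j]: is_ids[(j - n_is) % n_is] for j in range(n_is, n_analytes)
            }
        else:
            standard_maps[block_id] = {}

        intensities = 10.0 ** log_values

        # pooled QC rows: per-analyte mean of a random study-sample subset + noise
        if config.qc_count:
            subset_size = min(n_study, max(2, n_study // 3))
            subset = rng.choice(n_study, size=subset_size, replace=False)
            pooled = intensities[subset].mean(axis=0)
            qc = pooled[None, :] * 10.0 ** rng.normal(0.0, 0.02, size=(config.qc_count, n_analytes))
            matrix = np.vstack([intensities, qc])
        else:
            matrix = intensities

        blocks.append(AnalyteBlock(block_id=block_id, data=pd.DataFrame(matrix, columns=analyte_ids)))

    qc_ids = [f"QC{i + 1:02d}" for i in range(config.qc_count)]
    all_ids = sample_ids + qc_ids
    samples = pd.DataFrame(
        {
            "subject_id": sample_subjects + [GROUP_QC] * config.qc_count,
            "group": sample_groups + [GROUP_QC] * config.qc_count,
        },
        index=pd.Index(all_ids, name="sample_id"),
    )
    for b in blocks:
        b.data.index = samples.index

    dataset = MultiBlockDataset(blocks=blocks, samples=samples)

    if config.zero_rate > 0:
        zero_seed = int(rng.integers(0, 2**31 - 1))
        dataset = _inject(dataset, config.zero_rate, zero_seed, value=0.0)
    if config.missing_rate > 0:
        miss_seed = int(rng.integers(0, 2**31 - 1))
        dataset = inject_missingness(dataset, config.missing_rate, miss_seed)

    truth = GroundTruth(
        informative=informative,
        subject_map={sid: subj for sid, subj in zip(sample_ids, sample_subjects)},
        standard_maps=standard_maps,
    )
    return dataset, truth


def inject_missingness(dataset: MultiBlockDataset, rate: float, seed: int) -> MultiBlockDataset:
    """Set each study-sample intensity to missing independently with probability ``rate``.

    QC rows are exempt.  Deterministic given ``seed``.
    """
    if not 0 <= rate < 1:
        raise ConfigurationError(f"missing_rate must be in [0, 1), got {rate}")
    return _inject(dataset, rate, seed, value=np.nan)


def _inject(dataset: MultiBlockDataset, rate: float, seed: int, value: float) -> MultiBlockDataset:
    if rate == 0:
        return dataset
    rng = np.random.default_rng(seed)
    exempt = (dataset.samples["group"] == GROUP_QC).to_numpy()
    new_blocks = []
    for block in dataset.blocks:
        mask = rng.random(block.data.shape) < rate
        mask[exempt, :] = False
        # never blank an internal standard: they must stay positive for normalization
        is_cols = [j for j, c in enumerate(block.data.columns) if "_IS" in c]
        if is_cols:
            mask[:, is_cols] = False
        data = block.data.mask(pd.DataFrame(mask, index=block.data.index, columns=block.data.columns), value)
        new_blocks.append(block.with_data(data))
    return dataset.with_blocks(new_blocks)
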
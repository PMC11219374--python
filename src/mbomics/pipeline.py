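"""End-to-end study pipeline: preprocess, explore, split, model, screen.

Chains the package stages the way the underlying study design intends:

1. per-block preprocessing (normalize, 1/5-minimum impute, log10, autoscale),
   first fitted globally on all study samples for unsupervised exploration;
2. SUM-PCA on the autoscaled blocks; Duplex on the super scores with the
   same-subject constraint to fix common training and test sets;
3. preprocessing refitted on the training rows only and replayed on the
   held-out rows (no leakage) for supervised modelling;
4. PLS-DA per block, per modality, and on the fully fused matrix, with
   grouped-CV latent-variable selection and VIP>1 bookkeeping;
5. SO-CovSel-LDA with CV selection of per-block variable counts, optionally
   enumerated over every ordered block combination;
6. univariate Mann-Whitney screening of the selected panel on non-log
   intensities.

All randomness derives from one top-level seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datasets import MultiBlockDataset
from .errors import ConfigurationError
from .evaluate import confusion
from .fusion import fit_sum_pca, low_level_fuse
from .partition import SplitPlan, duplex_split
from .plsda import cv_select_lv, decode_labels, encode_labels, fit_plsda, predict_plsda
from .preprocess import apply_states, preprocess_dataset
from .simulate import SimConfig, generate_multiblock
from .socovsel import fit_so_covsel_lda, grid_select, predict_so_covsel, run_block_orders
from .enrich import univariate_screen

log = logging.getLogger("mbomics")


@dataclass
class PipelineConfig:
    """Tunable knobs of the end-to-end run (one seed drives everything)."""

    normalization: Mapping[str, str] | str = "total_ion_sum"
    test_fraction: float = 0.30
    sum_pca_components: int = 3
    max_lv: int = 10
    cv_folds: int = 10
    socovsel_grid: int = 3
    socovsel_folds: int = 5
    all_block_orders: bool = False
    seed: int = 0

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        try:
            return cls(**dict(d))
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from None


def load_config(path: str | Path) -> tuple[SimConfig, PipelineConfig]:
    """Read a YAML config with ``simulation`` and ``pipeline`` sections."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimConfig.from_dict(payload.get("simulation", {}))
    pipe = PipelineConfig.from_dict(payload.get("pipeline", {}))
    return sim, pipe


def _modality(block_id: str) -> str:
    return block_id.rsplit("_", 1)[0] if "_" in block_id else block_id


def plsda_mode_table(
    dataset_scaled: MultiBlockDataset,
    plan: SplitPlan,
    config: PipelineConfig,
    modes: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """PLS-DA per mode (block / modality fusion / full fusion).

    One row per mode with analyte count, chosen LV count, VIP>1 count, and
    training / CV / test accuracy, sensitivity, specificity (percent).
    """
    if modes is None:
        modes = {}
        for b in dataset_scaled.block_ids:
            modes[b] = [b]
        by_modality: dict[str, list[str]] = {}
        for b in dataset_scaled.block_ids:
            by_modality.setdefault(_modality(b), []).append(b)
        for name, members in by_modality.items():
            if len(members) > 1:
                modes[name] = members
        if len(dataset_scaled.block_ids) > 1:
            modes["fusion"] = list(dataset_scaled.block_ids)

    groups = dataset_scaled.groups()
    subjects = dataset_scaled.subjects()
    rows = []
    for name, block_ids in modes.items():
        sub = dataset_scaled.with_blocks([dataset_scaled[b] for b in block_ids])
        fused, _ = low_level_fuse(sub, weights="none")
        X_train = fused.loc[plan.train_samples]
        X_test = fused.loc[plan.test_samples]
        y_train = list(groups.loc[plan.train_samples])
        y_test = list(groups.loc[plan.test_samples])
        subj_train = list(subjects.loc[plan.train_samples])
        n_lv, _cv_report = cv_select_lv(
            X_train,
            y_train,
            subj_train,
            max_lv=min(config.max_lv, len(plan.train_samples) - 1, fused.shape[1]),
            folds=config.cv_folds,
            seed=config.seed,
        )
        model = fit_plsda(X_train, y_train, n_lv, training_subjects=subj_train)
        rep_train = confusion(y_train, predict_plsda(model, X_train)[0], "training")
        rep_test = confusion(y_test, predict_plsda(model, X_test)[0], "test")
        cv_row = _cv_report.loc[n_lv]
        rows.append(
            {
                "mode": name,
                "n_analytes": fused.shape[1],
                "n_vip_gt1": len(model.vip_above(1.0)),
                "n_lv": n_lv,
                "train_accuracy": rep_train.accuracy,
                "cv_accuracy": cv_row["cv_accuracy"],
                "test_accuracy": rep_test.accuracy,
                "train_sensitivity": rep_train.sensitivity,
                "cv_sensitivity": cv_row["cv_sensitivity"],
                "test_sensitivity": rep_test.sensitivity,
                "train_specificity": rep_train.specificity,
                "cv_specificity": cv_row["cv_specificity"],
                "test_specificity": rep_test.specificity,
            }
        )
    return pd.DataFrame(rows).set_index("mode")


def run_study(
    sim_config: SimConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    dataset: MultiBlockDataset | None = None,
    standard_maps: Mapping[str, Mapping[str, str]] | None = None,
) -> dict:
    """Run the full pipeline on a supplied or freshly simulated dataset.

    Returns a dict with the dataset, ground truth (when simulated), SUM-PCA
    model, split plan, PLS-DA mode table, SO-CovSel selection and reports,
    and the univariate screen of the selected panel.
    """
    config = pipeline_config or PipelineConfig()
    truth = None
    if dataset is None:
        sim_config = sim_config or SimConfig(seed=config.seed)
        dataset, truth = generate_multiblock(sim_config)
        if standard_maps is None and any(truth.standard_maps.values()):
            standard_maps = truth.standard_maps
    log.info("dataset: %d samples, blocks %s", len(dataset.samples), dataset.block_ids)

    # global preprocessing for exploration and splitting
    scaled_global, _ = preprocess_dataset(
        dataset, normalization=config.normalization, standard_maps=standard_maps
    )
    sum_pca = fit_sum_pca(
        scaled_global.subset(scaled_global.non_qc_ids), k=config.sum_pca_components
    )
    plan = duplex_split(
        sum_pca.super_scores,
        dataset.subjects(dataset.non_qc_ids),
        test_fraction=config.test_fraction,
    )
    log.info("Duplex: %d train / %d test samples", len(plan.train_samples), len(plan.test_samples))

    # supervised preprocessing: statistics from training rows only
    scaled, states = preprocess_dataset(
        dataset,
        normalization=config.normalization,
        standard_maps=standard_maps,
        fit_rows=plan.train_samples,
    )

    plsda_table = plsda_mode_table(scaled, plan, config)

    groups = dataset.groups()
    subjects = dataset.subjects()
    train = dataset.subset(plan.train_samples)
    y_train = list(groups.loc[plan.train_samples])
    subj_train = list(subjects.loc[plan.train_samples])
    scaled_train = scaled.subset(plan.train_samples)
    scaled_test = scaled.subset(plan.test_samples)
    order = tuple(dataset.block_ids)
    best_counts, grid_report = grid_select(
        scaled_train,
        y_train,
        subj_train,
        order,
        grid=[config.socovsel_grid] * len(order),
        folds=config.socovsel_folds,
        seed=config.seed,
    )
    so_model = fit_so_covsel_lda(
        scaled_train, y_train, order, best_counts, training_subjects=sorted(set(subj_train))
    )
    rep_train = confusion(y_train, predict_so_covsel(so_model, scaled_train), "training")
    y_test = list(groups.loc[plan.test_samples])
    rep_test = confusion(y_test, predict_so_covsel(so_model, scaled_test), "test")
    log.info(
        "SO-CovSel-LDA: counts %s, train %.2f%%, test %.2f%%",
        dict(zip(order, best_counts)),
        rep_train.accuracy,
        rep_test.accuracy,
    )

    order_table = None
    if config.all_block_orders:
        order_table = run_block_orders(
            scaled_train,
            y_train,
            scaled_test,
            y_test,
            n_vars_per_block=dict(zip(order, best_counts)),
            subject_ids=subj_train,
            folds=config.socovsel_folds,
            seed=config.seed,
        )

    # univariate screen of the selected panel on normalized+imputed (non-log) intensities
    panel = so_model.selected_ids
    screen = None
    if panel:
        pieces = []
        for block in dataset.block_ids:
            cols = [a for a in panel if a in scaled[block].data.columns]
            if not cols:
                continue
            blk, _ = _nonlog_block(dataset[block], config, standard_maps, block)
            pieces.append(blk[cols])
        values = pd.concat(pieces, axis=1).loc[dataset.non_qc_ids]
        screen = univariate_screen(values, list(groups.loc[dataset.non_qc_ids]), panel)

    return {
        "dataset": dataset,
        "ground_truth": truth,
        "preprocess_states": states,
        "sum_pca": sum_pca,
        "split_plan": plan,
        "plsda_table": plsda_table,
        "socovsel_counts": dict(zip(order, best_counts)),
        "socovsel_grid_report": grid_report,
        "socovsel_model": so_model,
        "socovsel_train_report": rep_train,
        "socovsel_test_report": rep_test,
        "block_order_table": order_table,
        "univariate_screen": screen,
    }


def _nonlog_block(raw_block, config, standard_maps, block_id):
    from .preprocess import impute_min_fraction, normalize_internal_standard, normalize_total_ion_sum, skip_normalization

    tag = (
        config.normalization
        if isinstance(config.normalization, str)
        else config.normalization[block_id]
    )
    if tag == "total_ion_sum":
        out = normalize_total_ion_sum(raw_block)
    elif tag == "internal_standard":
        out = normalize_internal_standard(raw_block, (standard_maps or {})[block_id])
    else:
        out = skip_normalization(raw_block)
    out, state = impute_min_fraction(out)
    return out.data, state
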
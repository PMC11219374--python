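"""Preprocessing chain: normalization, imputation, log10, autoscaling, state replay."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mbomics import (
    AnalyteBlock,
    DataError,
    PipelineOrderError,
    PreprocessState,
    apply_state,
    autoscale,
    impute_min_fraction,
    log_transform,
    normalize_internal_standard,
    normalize_total_ion_sum,
    preprocess_block,
    skip_normalization,
)


def _block(values, columns=None, stage="raw", block_id="B"):
    df = pd.DataFrame(values, columns=columns)
    df.index = [f"s{i}" for i in range(len(df))]
    return AnalyteBlock(block_id=block_id, data=df, stage=stage)


class TestTotalIonSum:
    def test_proportions(self):
        out = normalize_total_ion_sum(_block([[2.0, 3.0, 5.0]]))
        assert np.allclose(out.data.to_numpy(), [[0.2, 0.3, 0.5]])
        assert out.stage == "normalized"

    def test_missing_entries_untouched(self):
        out = normalize_total_ion_sum(_block([[1.0, np.nan, 3.0]]))
        assert np.allclose(out.data.iloc[0, [0, 2]], [0.25, 0.75])
        assert np.isnan(out.data.iloc[0, 1])

    def test_all_zero_row_errors_naming_sample(self):
        with pytest.raises(DataError, match="s1"):
            normalize_total_ion_sum(_block([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0]]))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(0.01, 1e6), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    def test_fully_observed_rows_sum_to_one(self, rows):
        out = normalize_total_ion_sum(_block(rows))
        assert np.allclose(out.data.sum(axis=1), 1.0, atol=1e-12)


class TestInternalStandard:
    def test_ratio(self):
        block = _block([[6.0, 2.0]], columns=["x", "std"])
        out = normalize_internal_standard(block, {"x": "std"})
        assert out.data.loc["s0", "x"] == pytest.approx(3.0)
        assert "std" not in out.data.columns

    def test_constant_standard_is_identity(self):
        block = _block([[4.0, 1.0], [7.0, 1.0]], columns=["x", "std"])
        out = normalize_internal_standard(block, {"x": "std"})
        assert np.allclose(out.data["x"], [4.0, 7.0])

    def test_per_class_division(self):
        block = _block([[8.0, 8.0, 2.0, 4.0]], columns=["a1", "a2", "s1", "s2"])
        out = normalize_internal_standard(block, {"a1": "s1", "a2": "s2"})
        assert np.allclose(out.data.loc["s0", ["a1", "a2"]], [4.0, 2.0])

    def test_unmapped_analyte_errors(self):
        block = _block([[8.0, 8.0, 2.0]], columns=["a1", "a2", "s1"])
        with pytest.raises(DataError, match="a2"):
            normalize_internal_standard(block, {"a1": "s1"})

    def test_nonpositive_standard_errors(self):
        block = _block([[8.0, 0.0]], columns=["a1", "s1"])
        with pytest.raises(DataError, match="s1"):
            normalize_internal_standard(block, {"a1": "s1"})


class TestImpute:
    def test_one_fifth_minimum(self):
        block = _block([[0.0], [2.0], [np.nan], [10.0]], stage="normalized")
        out, state = impute_min_fraction(block)
        assert np.allclose(out.data.iloc[:, 0], [0.4, 2.0, 0.4, 10.0])
        assert state.replacement.iloc[0] == pytest.approx(0.4)

    def test_clean_column_unchanged_and_idempotent(self):
        block = _block([[5.0], [7.0]], stage="normalized")
        out, _ = impute_min_fraction(block)
        assert np.allclose(out.data.iloc[:, 0], [5.0, 7.0])
        again, _ = impute_min_fraction(out.with_data(out.data, stage="normalized"))
        pd.testing.assert_frame_equal(again.data, out.data)

    def test_dead_analyte_listed_in_error(self):
        block = _block([[0.0, 1.0], [0.0, 2.0]], columns=["dead", "ok"], stage="normalized")
        with pytest.raises(DataError, match="dead"):
            impute_min_fraction(block)

    def test_output_has_no_missing_or_zero(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(size=(20, 8))
        vals[rng.random((20, 8)) < 0.3] = 0.0
        vals[rng.random((20, 8)) < 0.2] = np.nan
        out, _ = impute_min_fraction(_block(vals, stage="normalized"))
        arr = out.data.to_numpy()
        assert not np.isnan(arr).any() and (arr > 0).all()


class TestLogAndAutoscale:
    def test_log10_values(self):
        block = _block([[100.0], [1.0], [0.4]], stage="imputed")
        out = log_transform(block)
        assert np.allclose(out.data.iloc[:, 0], [2.0, 0.0, -0.3979400087])

    def test_log_rejects_nonpositive(self):
        with pytest.raises(DataError, match="impute"):
            log_transform(_block([[0.0]], stage="imputed"))

    def test_autoscale_column(self):
        block = _block([[1.0], [2.0], [3.0]], stage="log10")
        out, state = autoscale(block)
        assert np.allclose(out.data.iloc[:, 0], [-1.0, 0.0, 1.0])
        assert state.center.iloc[0] == pytest.approx(2.0)
        assert state.scale.iloc[0] == pytest.approx(1.0)  # n-1 denominator

    def test_autoscale_idempotent_on_zscores(self):
        rng = np.random.default_rng(1)
        block = _block(rng.normal(size=(30, 4)), stage="log10")
        once, _ = autoscale(block)
        twice, _ = autoscale(once.with_data(once.data, stage="log10"))
        assert np.allclose(once.data.to_numpy(), twice.data.to_numpy(), atol=1e-10)

    def test_constant_column_errors(self):
        with pytest.raises(DataError, match="zero-variance"):
            autoscale(_block([[1.0], [1.0], [1.0]], stage="log10"))

    def test_reference_rows_only(self):
        block = _block([[0.0], [2.0], [100.0]], stage="log10")
        out, _ = autoscale(block, reference_rows=["s0", "s1"])
        # mean 1, sd sqrt(2) from the two reference rows, applied to all rows
        assert np.allclose(out.data.iloc[:2, 0], [-1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert out.data.iloc[2, 0] == pytest.approx(99 / np.sqrt(2))


class TestPipelineOrder:
    def test_each_step_requires_its_stage(self):
        raw = _block([[1.0, 2.0]])
        with pytest.raises(PipelineOrderError):
            log_transform(raw)
        with pytest.raises(PipelineOrderError):
            autoscale(raw)
        normalized = skip_normalization(raw)
        with pytest.raises(PipelineOrderError):
            normalize_total_ion_sum(normalized)
        imputed, _ = impute_min_fraction(normalized)
        with pytest.raises(PipelineOrderError):
            impute_min_fraction(log_transform(imputed))


class TestState:
    def test_replay_reproduces_fit(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(mean=2.0, size=(25, 6))
        vals[rng.random((25, 6)) < 0.15] = np.nan
        block = _block(vals)
        fitted, state = preprocess_block(block, normalization="total_ion_sum")
        replayed = apply_state(block, state)
        assert np.allclose(fitted.data.to_numpy(), replayed.data.to_numpy(), atol=1e-12)
        assert replayed.stage == "autoscaled"

    def test_scaling_only_state(self):
        state = PreprocessState(
            block_id="B",
            center=pd.Series({"x": 2.0}),
            scale=pd.Series({"x": 1.0}),
        )
        block = _block([[4.0]], columns=["x"], stage="log10")
        out = apply_state(block, state)
        assert out.data.loc["s0", "x"] == pytest.approx(2.0)

    def test_missing_analyte_in_state_errors(self):
        state = PreprocessState(
            block_id="B",
            center=pd.Series({"x": 0.0}),
            scale=pd.Series({"x": 1.0}),
        )
        block = _block([[1.0, 2.0]], columns=["x", "y"], stage="log10")
        with pytest.raises(DataError, match="y"):
            apply_state(block, state)

    def test_state_round_trips_through_json(self, tmp_path):
        block = _block(np.random.default_rng(3).lognormal(size=(10, 3)), columns=["a", "b", "c"])
        _, state = preprocess_block(block, normalization="total_ion_sum")
        path = tmp_path / "state.json"
        state.to_json(path)
        loaded = PreprocessState.from_json(path)
        out1 = apply_state(block, state)
        out2 = apply_state(block, loaded)
        assert np.allclose(out1.data.to_numpy(), out2.data.to_numpy())

    def test_held_out_rows_use_training_statistics(self):
        rng = np.random.default_rng(4)
        block = _block(rng.lognormal(size=(20, 4)))
        train_rows = [f"s{i}" for i in range(15)]
        fitted, state = preprocess_block(block, normalization="none", fit_rows=train_rows)
        assert sorted(state.fitted_on) == sorted(train_rows)
        # training columns are centered; the full matrix generally is not
        assert np.allclose(fitted.data.loc[train_rows].mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(fitted.data.loc[train_rows].std(axis=0, ddof=1), 1.0, atol=1e-10)
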
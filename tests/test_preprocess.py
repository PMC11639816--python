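"""Preprocessing: cleaning, imputation, interpolation, masks, assembly."""

import numpy as np
import pandas as pd
import pytest

from oxytriage.preprocess import (
    FEATURE_COLUMNS,
    MASK_COLUMNS,
    MaskedMinuteSeries,
    assemble_features,
    clamp_outliers,
    derive_physiology,
    impute_chained,
    interpolate_minutes,
    merge_duplicates,
    one_hot_race,
    validate_interpolation,
)
from oxytriage.scoring import CLAMP_BOUNDS, VITALS


def _obs(rows):
    return pd.DataFrame(rows, columns=["patient_id", "admission_id", "charttime", "vital", "value"])


class TestMergeDuplicates:
    def test_partial_rows_merge(self):
        obs = _obs([
            ("p", "a", 10, "heart_rate", 80.0),
            ("p", "a", 10, "spo2", 97.0),
        ])
        merged = merge_duplicates(obs)
        assert len(merged) == 2
        assert set(merged["vital"]) == {"heart_rate", "spo2"}

    def test_identical_row_kept_once(self):
        row = ("p", "a", 5, "heart_rate", 80.0)
        merged = merge_duplicates(_obs([row, row]))
        assert len(merged) == 1

    def test_conflict_keeps_last_by_input_order(self, caplog):
        obs = _obs([
            ("p", "a", 5, "heart_rate", 80.0),
            ("p", "a", 5, "heart_rate", 90.0),
        ])
        merged = merge_duplicates(obs)
        assert len(merged) == 1
        assert merged["value"].iloc[0] == 90.0

    def test_null_does_not_displace_value(self):
        obs = _obs([
            ("p", "a", 5, "heart_rate", 80.0),
            ("p", "a", 5, "heart_rate", np.nan),
        ])
        assert merge_duplicates(obs)["value"].iloc[0] == 80.0

    def test_empty(self):
        assert merge_duplicates(_obs([])).empty

    def test_idempotent(self):
        obs = _obs([
            ("p", "a", 5, "heart_rate", 80.0),
            ("p", "a", 5, "heart_rate", 90.0),
            ("p", "a", 6, "spo2", 95.0),
        ])
        once = merge_duplicates(obs)
        twice = merge_duplicates(once)
        pd.testing.assert_frame_equal(once, twice)


class TestClampOutliers:
    @pytest.mark.parametrize(
        "vital, value, expect_missing",
        [
            ("heart_rate", 350.0, True),
            ("heart_rate", 300.0, False),
            ("spo2", 100.0, False),
            ("spo2", 101.0, True),
            ("temperature", -1.0, True),
            ("temperature", 60.0, False),
            ("respiratory_rate", -2.0, True),
        ],
    )
    def test_bounds(self, vital, value, expect_missing):
        obs = _obs([("p", "a", 0, vital, value)])
        out = clamp_outliers(obs)
        assert out["value"].isna().iloc[0] == expect_missing

    def test_idempotent_with_merge(self):
        obs = _obs([
            ("p", "a", 0, "heart_rate", 350.0),
            ("p", "a", 1, "spo2", 95.0),
        ])
        once = clamp_outliers(merge_duplicates(obs))
        twice = clamp_outliers(merge_duplicates(once))
        pd.testing.assert_frame_equal(once, twice)


class TestImputeChained:
    def test_no_missing_is_identity(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out, mask = impute_chained(table, seed=0)
        pd.testing.assert_frame_equal(out, table)
        assert mask.values.sum() == 0

    def test_linear_relation_recovered(self):
        # y = 2x exactly; one hidden y must come back near the line.
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 50, 200)
        y = 2.0 * x
        y_obs = y.copy()
        y_obs[17] = np.nan
        table = pd.DataFrame({"x": x, "y": y_obs})
        out, mask = impute_chained(table, seed=0)
        assert mask.loc[17, "y"] == 1
        assert int(mask.values.sum()) == 1
        assert abs(out.loc[17, "y"] - y[17]) <= 0.1 * (y.max() - y.min())

    def test_masks_flag_every_imputed_cell(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        holes = rng.random(table.shape) < 0.15
        hidden = table.mask(holes)
        out, mask = impute_chained(hidden, seed=1)
        assert out.notna().all().all()
        np.testing.assert_array_equal(mask.values, hidden.isna().astype(int).values)

    def test_fully_missing_column_is_error(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="fully missing"):
            impute_chained(table, seed=0)

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        hidden = table.mask(rng.random(table.shape) < 0.2)
        out1, _ = impute_chained(hidden, seed=7)
        out2, _ = impute_chained(hidden, seed=7)
        pd.testing.assert_frame_equal(out1, out2)


class TestInterpolateMinutes:
    def test_linear_midpoint(self):
        wide = pd.DataFrame({"charttime": [0, 10], "heart_rate": [60.0, 70.0]})
        out = interpolate_minutes(wide)
        assert len(out) == 11
        assert out.loc[out["charttime"] == 5, "heart_rate"].iloc[0] == 65.0
        assert out.loc[out["charttime"] == 5, "row_interpolated"].iloc[0] == 1
        assert out.loc[out["charttime"] == 0, "row_interpolated"].iloc[0] == 0

    def test_constant_fill(self):
        wide = pd.DataFrame({"charttime": [0, 8], "spo2": [95.0, 95.0]})
        out = interpolate_minutes(wide)
        assert (out["spo2"] == 95.0).all()

    def test_single_observation_constant_length_one(self):
        wide = pd.DataFrame({"charttime": [4], "spo2": [97.0]})
        out = interpolate_minutes(wide)
        assert len(out) == 1
        assert out["spo2"].iloc[0] == 97.0

    def test_masks_one_on_generated_minutes(self):
        wide = pd.DataFrame({"charttime": [0, 4], "heart_rate": [60.0, 64.0]})
        imask = pd.DataFrame({"heart_rate": [1, 0]})
        out = interpolate_minutes(wide, imput_mask=imask)
        np.testing.assert_array_equal(out["mask_heart_rate"], [1, 1, 1, 1, 0])

    def test_convex_hull_property(self):
        rng = np.random.default_rng(3)
        times = np.sort(rng.choice(np.arange(200), size=20, replace=False))
        values = rng.uniform(40, 160, size=20)
        wide = pd.DataFrame({"charttime": times, "heart_rate": values})
        out = interpolate_minutes(wide)
        assert out["heart_rate"].min() >= values.min() - 1e-9
        assert out["heart_rate"].max() <= values.max() + 1e-9

    def test_missing_values_rejected(self):
        wide = pd.DataFrame({"charttime": [0, 5], "spo2": [95.0, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            interpolate_minutes(wide)


class TestValidateInterpolation:
    def test_monotone_input_linear_extremes_equal_data(self):
        times = np.array([0, 10, 25, 40, 60], dtype=float)
        values = np.array([60, 70, 80, 90, 100], dtype=float)
        report = validate_interpolation(times, values)
        assert report.loc["linear", "minimal"] == values.min()
        assert report.loc["linear", "maximal"] == values.max()

    def test_oscillation_makes_spline_overshoot(self):
        times = np.array([0.0, 10.0, 20.0, 30.0, 40.0])
        values = np.array([95.0, 60.0, 98.0, 55.0, 99.0])
        report = validate_interpolation(times, values)
        assert (
            report.loc["cubic_spline", "maximal"] > values.max()
            or report.loc["cubic_spline", "minimal"] < values.min()
        )

    def test_linear_never_exceeds_observed_range(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            times = np.sort(rng.choice(np.arange(300), size=8, replace=False)).astype(float)
            values = rng.uniform(0, 200, size=8)
            report = validate_interpolation(times, values)
            assert report.loc["linear", "minimal"] >= values.min() - 1e-9
            assert report.loc["linear", "maximal"] <= values.max() + 1e-9

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            validate_interpolation(np.array([0.0, 1.0]), np.array([1.0, 2.0]))


class TestDerivePhysiology:
    def test_bmi_and_map_arithmetic(self):
        frame = pd.DataFrame(
            {
                "charttime": [0],
                "height": [175.0],
                "weight": [70.0],
                "systolic_bp": [120.0],
                "diastolic_bp": [80.0],
            }
        )
        out = derive_physiology(frame)
        assert out["bmi"].iloc[0] == pytest.approx(22.9)
        assert out["map"].iloc[0] == pytest.approx(93.3)

    def test_mask_propagation(self):
        frame = pd.DataFrame(
            {
                "charttime": [0, 1],
                "height": [170.0, 170.0],
                "weight": [80.0, 80.0],
                "systolic_bp": [120.0, 118.0],
                "diastolic_bp": [70.0, 72.0],
                "mask_systolic_bp": [1, 0],
                "mask_diastolic_bp": [0, 0],
                "mask_height": [0, 0],
                "mask_weight": [1, 1],
            }
        )
        out = derive_physiology(frame)
        np.testing.assert_array_equal(out["mask_map"], [1, 0])
        np.testing.assert_array_equal(out["mask_bmi"], [1, 1])

    def test_inverted_pressures_warn_but_compute(self, caplog):
        frame = pd.DataFrame(
            {
                "charttime": [0],
                "height": [170.0],
                "weight": [70.0],
                "systolic_bp": [60.0],
                "diastolic_bp": [90.0],
            }
        )
        with caplog.at_level("WARNING"):
            out = derive_physiology(frame)
        assert out["map"].iloc[0] == pytest.approx(80.0)
        assert "DBP > SBP" in caplog.text


class TestAssembleFeatures:
    @staticmethod
    def _series():
        n = 6
        frame = pd.DataFrame(
            {
                "charttime": np.arange(n),
                "row_interpolated": np.zeros(n, dtype=np.int8),
                "respiratory_rate": np.full(n, 15.0),
                "spo2": np.array([98.0, 97, 95, 92, 88, 84]),
                "heart_rate": np.full(n, 75.0),
                "systolic_bp": np.full(n, 117.0),
                "diastolic_bp": np.full(n, 70.0),
                "temperature": np.full(n, 37.0),
            }
        )
        for v in VITALS:
            frame[f"mask_{v}"] = 0
        frame["height"] = 175.0
        frame["weight"] = 70.0
        frame["mask_height"] = 0
        frame["mask_weight"] = 0
        frame = derive_physiology(frame)
        return MaskedMinuteSeries(
            admission_id="a1",
            patient_id="p1",
            demographics={
                "age": 40.0,
                "gender": 1.0,
                "race": "white",
                "height": 175.0,
                "weight": 70.0,
                "copd": False,
            },
            frame=frame,
        )

    def test_schema_is_41_features(self, matrices):
        table = assemble_features(self._series(), *matrices)
        assert len(FEATURE_COLUMNS) == 41
        assert list(table.columns[:41]) == list(FEATURE_COLUMNS)
        assert {"label", "patient_id", "admission_id", "charttime", "row_interpolated"} <= set(
            table.columns
        )

    def test_all_original_has_zero_masks(self, matrices):
        table = assemble_features(self._series(), *matrices)
        assert (table[list(MASK_COLUMNS)].to_numpy() == 0).all()

    def test_tags_in_range_and_labels_follow_spo2(self, matrices):
        table = assemble_features(self._series(), *matrices)
        tags = table[[f"tag_{v}" for v in VITALS]].to_numpy()
        assert tags.min() >= 0 and tags.max() <= 3
        np.testing.assert_array_equal(table["label"], [0, 0, 1, 2, 3, 3])

    def test_unknown_race_maps_to_zeros(self):
        encoded = one_hot_race("martian")
        assert set(encoded.values()) == {0.0}
        assert sum(one_hot_race("white").values()) == 1.0


class TestPipelineProperties:
    def test_zero_missing_and_clamped(self, small_processed):
        feats = small_processed[list(FEATURE_COLUMNS)]
        assert not feats.isna().any().any()
        for vital, (lo, hi) in CLAMP_BOUNDS.items():
            assert small_processed[vital].between(lo, hi).all()

    def test_label_distribution_stable(self, small_cohort, small_processed):
        before = small_cohort.label_shares()
        after = (
            small_processed["label"].value_counts(normalize=True)
            .reindex(range(4), fill_value=0)
            .to_numpy()
        )
        assert np.abs(before - after).max() <= 0.05

    def test_mask_sound_on_interpolated_rows(self, small_processed):
        interp = small_processed["row_interpolated"] == 1
        for v in VITALS:
            assert (small_processed.loc[interp, f"mask_{v}"] == 1).all()

    def test_demographic_masks_never_flag_interpolation(self, small_processed):
        interp = small_processed["row_interpolated"] == 1
        # height/weight are admission-constant; interpolation alone must not
        # mark them synthetic (this cohort has complete demographics)
        assert (small_processed.loc[interp, "mask_height"] == 0).all()
        assert (small_processed.loc[interp, "mask_weight"] == 0).all()
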
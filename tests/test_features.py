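"""Tests for feature construction and the preprocessing stack."""

import numpy as np
import pandas as pd
import pytest

from gazerel.errors import InputError, SchemaError
from gazerel.features import (
    CATEGORY_FEATURES,
    FeatureMatrix,
    FeatureSchema,
    assemble_matrix,
    build_feature_group,
    deduplicate_features,
    impute_median_mode,
    impute_regression,
    remove_constant_features,
)
from gazerel.simulate import PatientCase


SERIES = [(10.0, 100.0), (20.0, 120.0), (30.0, 110.0)]


class TestBuildFeatureGroup:
    @pytest.mark.parametrize(
        "category,expected",
        [("labs", 35), ("vitals", 35), ("ventilator", 31),
         ("medications", 9), ("cultures", 4), ("procedures", 4), ("intake_output", 2)],
    )
    def test_group_sizes(self, category, expected):
        feats = build_feature_group(SERIES, category, prediction_time_h=48.0)
        assert len(feats) == expected
        assert list(feats) == list(CATEGORY_FEATURES[category])

    def test_named_lab_features(self):
        feats = build_feature_group(SERIES, "labs", prediction_time_h=48.0)
        assert feats["first_value"] == 100.0
        assert feats["last_value"] == 110.0
        assert feats["highest_value"] == 120.0
        assert feats["lowest_value"] == 100.0
        assert feats["diff_last_two"] == -10.0
        assert feats["ever_measured"] == 1.0

    def test_single_point_series_degenerates(self):
        feats = build_feature_group([(5.0, 42.0)], "labs", prediction_time_h=48.0)
        assert feats["first_value"] == feats["last_value"] == 42.0
        assert feats["highest_value"] == feats["lowest_value"] == 42.0
        assert np.isnan(feats["diff_last_two"])
        assert np.isnan(feats["std_value"])

    def test_unsorted_series_rejected(self):
        with pytest.raises(InputError, match="nondecreasing"):
            build_feature_group([(20.0, 1.0), (10.0, 2.0)], "labs", 48.0)

    def test_empty_series_rejected(self):
        with pytest.raises(InputError):
            build_feature_group([], "labs", 48.0)

    def test_medication_features_by_hand(self):
        # doses 5 at 10h and 7 at 40h; prediction 48h; admission 0h
        feats = build_feature_group([(10.0, 5.0), (40.0, 7.0)], "medications", 48.0)
        assert feats["ever_given"] == 1.0
        assert feats["n_administrations"] == 2.0
        assert feats["n_administrations_24h"] == 1.0
        assert feats["hours_since_last_dose"] == 8.0
        assert feats["cumulative_dose"] == 12.0
        assert feats["dose_trend"] == 2.0
        assert feats["n_distinct_days"] == 2.0


def _case(case_id: str, series, diagnosis="AKF", demo=None):
    demo = demo or {"age": 60.0, "sex": 1.0, "height": 170.0, "weight": 80.0,
                    "race": 2.0, "admission_unit": 0.0}
    return PatientCase(case_id=case_id, diagnosis=diagnosis, demographics=demo, series=series)


SCHEMA_COUNTS = {"labs": 2, "ventilator": 1, "medications": 3, "cultures": 1,
                 "intake_output": 1, "demographics": 6, "diagnosis": 1,
                 "vitals": 0, "procedures": 0}


class TestAssembleMatrix:
    def test_single_lab_width(self):
        schema = FeatureSchema.from_counts({"labs": 1, "demographics": 0, "diagnosis": 0})
        case = _case("c0", {"lab_00": SERIES}, demo={})
        fm = assemble_matrix([case], schema)
        assert fm.values.shape == (1, 35)

    def test_mixed_inventory_width_arithmetic(self):
        # 2 labs x 35 + 1 vent x 31 + 3 meds x 9 + 1 culture x 4 + 1 I/O x 2
        # + 6 demographics + 1 diagnosis = 141
        schema = FeatureSchema.from_counts(SCHEMA_COUNTS)
        assert schema.width == 2 * 35 + 31 + 3 * 9 + 4 + 2 + 7 == 141

    def test_empty_cohort_keeps_full_width(self):
        schema = FeatureSchema.from_counts(SCHEMA_COUNTS)
        fm = assemble_matrix([], schema)
        assert fm.values.shape == (0, 141)

    def test_absent_variable_fills_group_with_missing(self):
        schema = FeatureSchema.from_counts({"labs": 2, "demographics": 0, "diagnosis": 0})
        case = _case("c0", {"lab_00": SERIES}, demo={})
        fm = assemble_matrix([case], schema)
        group = fm.values[schema.group_columns("lab_01")]
        assert group.isna().all().all()
        assert fm.values.loc["c0", "lab_00::ever_measured"] == 1.0

    def test_out_of_schema_variable_rejected(self):
        schema = FeatureSchema.from_counts({"labs": 1, "demographics": 0, "diagnosis": 0})
        case = _case("c0", {"vit_00": SERIES}, demo={})
        with pytest.raises(SchemaError, match="vit_00"):
            assemble_matrix([case], schema)


def _fm(data: dict[str, list[float]]) -> FeatureMatrix:
    """Ad-hoc matrix over lab variables, one feature column per key."""
    n_vars = len(data)
    schema = FeatureSchema.from_counts({"labs": n_vars, "demographics": 0, "diagnosis": 0})
    df = pd.DataFrame(index=[f"c{i}" for i in range(len(next(iter(data.values()))))],
                      columns=schema.columns, dtype=float)
    for k, (var, _cat) in zip(data, schema.variables):
        df[f"{var}::first_value"] = data[k]
    # keep only the populated columns so tests stay small
    keep = [f"{var}::first_value" for var, _ in schema.variables]
    return FeatureMatrix(df[keep], schema)


class TestPreprocessing:
    def test_constant_column_removed(self):
        fm = _fm({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 2.0]})
        out, removed = remove_constant_features(fm)
        assert removed == ["lab_00::first_value"]
        assert list(out.values.columns) == ["lab_01::first_value"]

    def test_constant_removal_counts_on_random_fixture(self, rng):
        data = {f"v{i}": list(rng.normal(size=10)) for i in range(6)}
        for i in (1, 4):
            data[f"v{i}"] = [3.14] * 10
        out, removed = remove_constant_features(_fm(data))
        assert len(removed) == 2
        assert out.values.shape[1] == 4

    def test_constant_removal_idempotent(self, rng):
        fm = _fm({"a": [1, 1, 1], "b": [1, 2, 3]})
        once, _ = remove_constant_features(fm)
        twice, removed = remove_constant_features(once)
        assert removed == []
        assert once.values.equals(twice.values)

    def test_duplicates_keep_canonical_first(self):
        fm = _fm({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [0.0, 0.0, 1.0]})
        out, classes = deduplicate_features(fm)
        assert list(out.values.columns) == ["lab_00::first_value", "lab_02::first_value"]
        assert classes == [["lab_00::first_value", "lab_01::first_value"]]

    def test_three_way_duplicate_single_survivor(self):
        fm = _fm({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [1.0, 2.0]})
        out, classes = deduplicate_features(fm)
        assert out.values.shape[1] == 1
        assert len(classes[0]) == 3

    def test_nan_columns_compare_equal_for_dedup(self):
        fm = _fm({"a": [1.0, np.nan], "b": [1.0, np.nan], "c": [1.0, 0.0]})
        out, _ = deduplicate_features(fm)
        assert out.values.shape[1] == 2

    def test_no_duplicates_identity(self, rng):
        fm = _fm({f"v{i}": list(rng.normal(size=8)) for i in range(4)})
        out, classes = deduplicate_features(fm)
        assert classes == []
        assert out.values.equals(fm.values)

    def test_dedup_matches_pairwise_oracle(self, rng):
        cols = {f"v{i}": list(rng.integers(0, 2, size=6).astype(float)) for i in range(8)}
        fm = _fm(cols)
        out, _ = deduplicate_features(fm)
        kept = out.values
        # oracle: brute-force pairwise comparison of retained columns
        arr = kept.to_numpy()
        for i in range(arr.shape[1]):
            for j in range(i + 1, arr.shape[1]):
                assert not np.array_equal(arr[:, i], arr[:, j])

    def test_median_imputation_by_hand(self):
        fm = _fm({"a": [1.0, np.nan, 3.0]})
        out = impute_median_mode(fm)
        assert out.values.iloc[1, 0] == 2.0

    def test_imputation_identity_when_complete(self, rng):
        fm = _fm({f"v{i}": list(rng.normal(size=6)) for i in range(3)})
        assert impute_median_mode(fm).values.equals(fm.values)
        assert impute_regression(fm).values.equals(fm.values)

    def test_mode_imputation_with_tie_break(self):
        schema = FeatureSchema.from_counts(
            {"demographics": 2, "diagnosis": 0, "labs": 0}
        )
        df = pd.DataFrame(
            {"age::value": [50.0, 60.0, 70.0, 55.0], "sex::value": [0.0, 0.0, 1.0, np.nan]},
            index=list("abcd"),
        )
        fm = FeatureMatrix(df, schema)
        out = impute_median_mode(fm)
        assert out.values.loc["d", "sex::value"] == 0.0  # mode (and smallest on ties)

    def test_regression_imputation_recovers_exact_linear_relation(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0, 12.0]
        fm = _fm({"x": x, "y": y})
        out = impute_regression(fm)
        assert out.values.iloc[3, 1] == pytest.approx(8.0, abs=1e-6)

    def test_all_missing_column_falls_back_to_zero(self):
        fm = _fm({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        out = impute_regression(fm)
        assert (out.values.iloc[:, 0] == 0.0).all()

    def test_observed_cells_bit_identical_after_both_imputations(self, rng):
        vals = rng.normal(size=(8, 4))
        mask = rng.random((8, 4)) < 0.25
        vals[mask] = np.nan
        fm = _fm({f"v{i}": list(vals[:, i]) for i in range(4)})
        for impute in (impute_median_mode, impute_regression):
            out = impute(fm)
            observed = ~fm.values.isna().to_numpy()
            assert np.array_equal(
                out.values.to_numpy()[observed], fm.values.to_numpy()[observed]
            )
            assert not out.values.isna().any().any()
            assert out.values.shape == fm.values.shape
            assert list(out.values.columns) == list(fm.values.columns)
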
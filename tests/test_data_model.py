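import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maxminus_dropout.data_model import (BOOLEAN, CONTINUOUS, ClinicalTable,
                                         FeatureSchema, SchemaError,
                                         ValidationError,
                                         filter_rows_by_missingness, read_table,
                                         stratified_split, write_table)


class TestSchema:
    def test_duplicate_names_rejected(self):
        with pytest.raises(SchemaError):
            FeatureSchema(("a", "a"), (BOOLEAN, BOOLEAN), ("x", "y"))

    def test_single_class_rejected(self):
        with pytest.raises(SchemaError):
            FeatureSchema(("a",), (BOOLEAN,), ("only",))

    def test_type_count_must_match(self):
        with pytest.raises(SchemaError):
            FeatureSchema(("a", "b"), (BOOLEAN,), ("x", "y"))


class TestTableInvariants:
    def test_non_binary_boolean_rejected(self, small_schema):
        values = np.array([[2.0, 0.0, 1.0, 50.0]])
        with pytest.raises(ValidationError, match="dry_mouth"):
            ClinicalTable(values, np.zeros((1, 4), bool),
                          np.array(["dampness_heat"], object), small_schema)

    def test_unknown_label_rejected(self, small_schema):
        values = np.array([[1.0, 0.0, 1.0, 50.0]])
        with pytest.raises(ValidationError, match="mystery"):
            ClinicalTable(values, np.zeros((1, 4), bool),
                          np.array(["mystery"], object), small_schema)

    def test_masked_cells_exempt_from_binary_check(self, small_schema):
        values = np.array([[np.nan, 0.0, 1.0, 50.0]])
        mask = np.array([[True, False, False, False]])
        table = ClinicalTable(values, mask, np.array(["dampness_heat"], object),
                              small_schema)
        assert table.missing_per_row().tolist() == [1]


class TestCsvRoundTrip:
    def test_missing_cells_become_empty_and_back(self, small_table, tmp_path):
        path = tmp_path / "data.csv"
        write_table(small_table, path)
        text = path.read_text()
        assert text.count(",,") + text.count(",\n") >= 1  # empties present
        back = read_table(path, small_table.schema)
        assert np.array_equal(back.missing_mask, small_table.missing_mask)
        observed = ~small_table.missing_mask
        assert np.array_equal(back.values[observed], small_table.values[observed])
        assert np.array_equal(back.labels, small_table.labels)

    def test_missing_cell_count_preserved(self, small_table, tmp_path):
        path = tmp_path / "data.csv"
        write_table(small_table, path)
        back = read_table(path, small_table.schema)
        assert back.missing_mask.sum() == small_table.missing_mask.sum() == 4

    def test_empty_table_writes_header_only(self, small_schema, tmp_path):
        table = ClinicalTable(np.empty((0, 4)), np.empty((0, 4), bool),
                              np.empty((0,), object), small_schema)
        path = tmp_path / "empty.csv"
        write_table(table, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",") == list(small_schema.feature_names) + ["label"]

    def test_non_binary_value_reported_with_csv_row(self, small_schema, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("dry_mouth,thirst,numbness,age,label\n"
                        "1,0,1,50,dampness_heat\n"
                        "2,0,1,50,dampness_heat\n")
        with pytest.raises(ValidationError, match="row 3"):
            read_table(path, small_schema)

    def test_unknown_column_is_schema_error(self, small_schema, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("dry_mouth,thirst,numbness,age,label,extra\n")
        with pytest.raises(SchemaError, match="extra"):
            read_table(path, small_schema)

    def test_na_markers_case_insensitive(self, small_schema, tmp_path):
        path = tmp_path / "na.csv"
        path.write_text("dry_mouth,thirst,numbness,age,label\n"
                        "NA,nan,,50,dampness_heat\n")
        table = read_table(path, small_schema)
        assert table.missing_mask[0].tolist() == [True, True, True, False]


class TestFilterRows:
    def test_boundary_inclusive(self, small_schema):
        values = np.full((2, 4), np.nan)
        values[0, 3] = 50.0  # row 0: 3 missing; row 1: all 4 missing
        mask = np.isnan(values)
        table = ClinicalTable(values, mask,
                              np.array(["dampness_heat"] * 2, object), small_schema)
        kept = filter_rows_by_missingness(table, max_missing=3)
        assert kept.n_rows == 1
        assert kept.missing_per_row().tolist() == [3]

    def test_vacuous_filter_keeps_order(self, small_table):
        kept = filter_rows_by_missingness(small_table, small_table.n_features)
        assert np.array_equal(kept.labels, small_table.labels)
        obs = ~small_table.missing_mask
        assert np.array_equal(kept.values[obs], small_table.values[obs])


def _balanced_table(n: int, n_classes: int = 2, seed: int = 0) -> ClinicalTable:
    rng = np.random.default_rng(seed)
    schema = FeatureSchema(("f0",), (CONTINUOUS,),
                           tuple(f"c{i}" for i in range(n_classes)),
                           continuous_ranges={"f0": (0.0, 1.0)})
    labels = np.array([f"c{i % n_classes}" for i in range(n)], object)
    return ClinicalTable(rng.random((n, 1)), np.zeros((n, 1), bool), labels, schema)


class TestStratifiedSplit:
    @pytest.mark.parametrize("n,expected_train,expected_test",
                             [(1920, 1344, 576), (683, 478, 205), (768, 537, 231)])
    def test_seventy_thirty_counts(self, n, expected_train, expected_test):
        table = _balanced_table(n, n_classes=7 if n == 1920 else 2)
        split = stratified_split(table, 0.7, seed=0)
        assert len(split.train_indices) == expected_train
        assert len(split.test_indices) == expected_test

    def test_reproducible_and_seed_sensitive(self):
        table = _balanced_table(100)
        a = stratified_split(table, 0.7, seed=5)
        b = stratified_split(table, 0.7, seed=5)
        c = stratified_split(table, 0.7, seed=6)
        assert np.array_equal(a.train_indices, b.train_indices)
        assert not np.array_equal(a.train_indices, c.train_indices)
        assert len(a.train_indices) == len(c.train_indices)

    def test_partition_covers_all_rows(self):
        table = _balanced_table(101, n_classes=3)
        split = stratified_split(table, 0.7, seed=1)
        union = np.sort(np.concatenate([split.train_indices, split.test_indices]))
        assert np.array_equal(union, np.arange(101))

    def test_stratification_preserves_class_balance(self):
        table = _balanced_table(200, n_classes=4)
        split = stratified_split(table, 0.7, seed=2)
        train_labels = table.labels[split.train_indices]
        counts = {c: int((train_labels == c).sum()) for c in table.schema.class_labels}
        assert set(counts.values()) == {35}  # 0.7 * 50 per class

    def test_empty_class_rejected(self):
        schema = FeatureSchema(("f0",), (CONTINUOUS,), ("a", "b", "ghost"))
        table = ClinicalTable(np.zeros((4, 1)), np.zeros((4, 1), bool),
                              np.array(["a", "a", "b", "b"], object), schema)
        with pytest.raises(ValidationError, match="ghost"):
            stratified_split(table, 0.7, seed=0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(n=st.integers(min_value=2, max_value=500),
           frac=st.floats(min_value=0.1, max_value=0.9))
    def test_train_size_is_floor_of_fraction(self, n, frac):
        table = _balanced_table(n)
        split = stratified_split(table, frac, seed=0)
        assert len(split.train_indices) == math.floor(frac * n)
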
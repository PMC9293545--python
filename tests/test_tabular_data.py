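import io

import pytest
from hypothesis import given, settings, strategies as st

from ripperlearn.errors import DataParseError, SchemaError, ValidationError
from ripperlearn.tabular_data import (
    BAND_TABLE,
    MISSING,
    UNBANDED,
    AttributeSpec,
    Dataset,
    DatasetSchema,
    Instance,
    cleveland_schema,
    dataset_to_csv_text,
    discretize,
    load_cleveland,
    read_csv_dataset,
    write_csv_dataset,
)


class TestSchemaTypes:
    def test_categorical_needs_categories(self):
        with pytest.raises(ValidationError):
            AttributeSpec("a", "categorical")

    def test_numeric_rejects_categories(self):
        with pytest.raises(ValidationError):
            AttributeSpec("a", "numeric", categories=("x",))

    def test_duplicate_names_rejected(self):
        a = AttributeSpec("a", "numeric")
        with pytest.raises(SchemaError):
            DatasetSchema((a, a), AttributeSpec("y", "categorical", ("0", "1")))

    def test_class_not_among_predictors(self):
        a = AttributeSpec("a", "numeric")
        with pytest.raises(SchemaError):
            DatasetSchema((a,), AttributeSpec("a", "categorical", ("0", "1")))

    def test_cleveland_schema_has_13_predictors(self):
        schema = cleveland_schema()
        assert len(schema.attributes) == 13
        assert schema.class_attribute.name == "num"


class TestReadCsv:
    def test_sample_rows_parse(self, table3_csv):
        ds = read_csv_dataset(table3_csv, cleveland_schema())
        assert len(ds) == 2
        assert set(ds.labels()) == {"0", "1"}
        first = ds.instances[0]
        assert first.values["thal"] == "7"
        assert first.values["ca"] == 0.0
        assert first.values["oldpeak"] == pytest.approx(1.6)
        assert first.values["restecg"] is MISSING

    def test_header_only_yields_empty_dataset(self, simple_schema):
        text = "x1,x2,x3,c1,y\n"
        ds = read_csv_dataset(io.StringIO(text), simple_schema)
        assert len(ds) == 0

    def test_question_mark_becomes_missing(self, simple_schema):
        text = "x1,x2,x3,c1,y\n1,?,3,a,0\n"
        ds = read_csv_dataset(io.StringIO(text), simple_schema)
        assert ds.instances[0].values["x2"] is MISSING
        assert ds.instances[0].values["x1"] == 1.0

    def test_header_order_insensitive(self, simple_schema):
        text = "y,c1,x3,x2,x1\n0,a,3,2,1\n"
        ds = read_csv_dataset(io.StringIO(text), simple_schema)
        assert ds.instances[0].values["x1"] == 1.0
        assert ds.instances[0].label == "0"

    def test_missing_column_named_in_error(self, simple_schema):
        text = "x1,x2,c1,y\n1,2,a,0\n"
        with pytest.raises(SchemaError, match="x3"):
            read_csv_dataset(io.StringIO(text), simple_schema)

    def test_extra_column_named_in_error(self, simple_schema):
        text = "x1,x2,x3,c1,zz,y\n1,2,3,a,9,0\n"
        with pytest.raises(SchemaError, match="zz"):
            read_csv_dataset(io.StringIO(text), simple_schema)

    def test_bad_numeric_cell_addressed(self, simple_schema):
        text = "x1,x2,x3,c1,y\n1,2,3,a,0\n1,abc,3,a,0\n"
        with pytest.raises(DataParseError, match="row 2.*x2"):
            read_csv_dataset(io.StringIO(text), simple_schema)

    def test_round_trip(self, simple_schema):
        text = "x1,x2,x3,c1,y\n1,?,3.5,a,0\n4,5,6,?,1\n"
        ds = read_csv_dataset(io.StringIO(text), simple_schema)
        again = read_csv_dataset(io.StringIO(dataset_to_csv_text(ds)), simple_schema)
        assert [i.values for i in again.instances] == [i.values for i in ds.instances]
        assert again.labels() == ds.labels()


class TestLoadCleveland:
    UCI_ROW = "55.0,0.0,3.0,115.0,322.0,0.0,0.0,160.0,0.0,1.6,2.0,0.0,7.0,{cls}\n"

    def _load(self, tmp_path, text):
        path = tmp_path / "cleveland.data"
        path.write_text(text)
        return load_cleveland(path)

    def test_class_zero_is_healthy(self, tmp_path):
        ds = self._load(tmp_path, self.UCI_ROW.format(cls="0"))
        assert ds.instances[0].label == "0"

    def test_raw_class_three_collapses_to_one(self, tmp_path):
        ds = self._load(tmp_path, self.UCI_ROW.format(cls="3"))
        assert ds.instances[0].label == "1"

    def test_labels_subset_of_binary(self, tmp_path):
        rows = "".join(self.UCI_ROW.format(cls=c) for c in "0123401234")
        ds = self._load(tmp_path, rows)
        assert set(ds.labels()) <= {"0", "1"}

    def test_missing_marker_preserved(self, tmp_path):
        row = "55.0,0.0,3.0,115.0,322.0,0.0,0.0,160.0,0.0,1.6,2.0,?,7.0,0\n"
        ds = self._load(tmp_path, row)
        assert ds.instances[0].values["ca"] is MISSING

    def test_wrong_column_count_rejected(self, tmp_path):
        with pytest.raises(SchemaError):
            self._load(tmp_path, "1.0,2.0,3.0\n")

    def test_record_count_of_uci_sized_file(self, tmp_path):
        from ripperlearn.synth_data import make_cleveland_like
        from ripperlearn.tabular_data import CLEVELAND_COLUMNS

        synth = make_cleveland_like(303, seed=7)
        lines = []
        for inst in synth.instances:
            cells = []
            for spec in synth.schema.attributes:
                v = inst.values[spec.name]
                cells.append(f"{float(v):.1f}")
            cells.append(inst.label)
            lines.append(",".join(cells))
        ds = self._load(tmp_path, "\n".join(lines) + "\n")
        assert len(ds) == 303
        assert len(CLEVELAND_COLUMNS) == 14

    def test_header_bearing_csv_accepted(self, table3_csv):
        ds = load_cleveland(table3_csv)
        assert len(ds) == 2


class TestDiscretize:
    @pytest.mark.parametrize(
        "attr,value,expected",
        [
            ("cholesterol", 322, "Very higher"),
            ("bp", 115, "Lower"),
            ("cholesterol", 230, "Medium"),  # overlap: first listed band wins
            ("age", 43, "Middle"),  # 35-45 precedes 40-58
            ("bp", 145, "Medium"),  # 124-153 precedes 142-172
            ("blood_sugar", 120, "Yes"),
            ("ecg", 0.4, "Abnormal"),
            ("thallium", 7, "Reversible defect"),
            ("chest_pain", 1, "Typical angina"),
            ("gender", 0, "Female"),
            ("smoking", 10, "Lower"),
            ("family_history", 0, "No"),
            ("medical_records", 2, "Yes"),
        ],
    )
    def test_band_labels(self, attr, value, expected):
        assert discretize(attr, value) == expected

    def test_first_match_equals_enumeration(self):
        # oracle: enumerate all matching bands, take the first in declared order
        for value in [150, 188, 200, 217, 250, 260, 281, 300, 307, 400]:
            matching = [b.label for b in BAND_TABLE["cholesterol"] if b.holds(value)]
            assert discretize("cholesterol", value) == matching[0]

    def test_gap_returns_unbanded_not_exception(self):
        assert discretize("thallium", 5) is UNBANDED
        assert discretize("chest_pain", 9) is UNBANDED

    def test_missing_is_unbanded(self):
        assert discretize("cholesterol", MISSING) is UNBANDED

    def test_unknown_attribute_raises(self):
        with pytest.raises(LookupError):
            discretize("vessel", 1)

    @pytest.mark.parametrize("attr", ["cholesterol", "bp", "ecg", "age", "smoking", "blood_sugar"])
    def test_total_on_covering_attributes(self, attr):
        for value in [v / 10.0 for v in range(-100, 6000, 7)]:
            assert discretize(attr, value) is not UNBANDED


class TestValidate:
    def test_bad_category_caught(self, simple_schema):
        ds = Dataset(
            simple_schema,
            [Instance({"x1": 1.0, "x2": 2.0, "x3": 3.0, "c1": "zz"}, "0")],
        )
        with pytest.raises(ValidationError, match="c1"):
            ds.validate()

    def test_missing_ok(self, simple_schema):
        ds = Dataset(
            simple_schema,
            [Instance({"x1": MISSING, "x2": 2.0, "x3": 3.0, "c1": MISSING}, "1")],
        )
        ds.validate()


@settings(max_examples=30, deadline=None)
@given(
    rows=st.lists(
        st.tuples(
            st.one_of(st.none(), st.integers(0, 100)),
            st.one_of(st.none(), st.integers(0, 100)),
            st.one_of(st.none(), st.integers(0, 100)),
            st.one_of(st.none(), st.sampled_from(["a", "b", "c"])),
            st.sampled_from(["0", "1"]),
        ),
        max_size=12,
    )
)
def test_csv_round_trip_property(rows):
    schema = DatasetSchema(
        attributes=(
            AttributeSpec("x1", "numeric"),
            AttributeSpec("x2", "numeric"),
            AttributeSpec("x3", "numeric"),
            AttributeSpec("c1", "categorical", ("a", "b", "c")),
        ),
        class_attribute=AttributeSpec("y", "categorical", ("0", "1")),
    )
    instances = [
        Instance(
            {
                "x1": MISSING if x1 is None else float(x1),
                "x2": MISSING if x2 is None else float(x2),
                "x3": MISSING if x3 is None else float(x3),
                "c1": MISSING if c1 is None else c1,
            },
            y,
        )
        for x1, x2, x3, c1, y in rows
    ]
    ds = Dataset(schema, instances)
    again = read_csv_dataset(io.StringIO(dataset_to_csv_text(ds)), schema)
    assert [i.values for i in again.instances] == [i.values for i in ds.instances]
    assert again.labels() == ds.labels()
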
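"""Tabular dataset schemas, CSV / Cleveland readers and the clinical band discretizer.

Datasets are plain in-memory objects: a :class:`DatasetSchema` describing the
predictor columns plus a categorical class column, and a list of
:class:`Instance` rows.  Missing values are represented by the :data:`MISSING`
sentinel (written as ``?`` on disk) and are never imputed.

The module also ships :data:`BAND_TABLE`, the ordered clinical band
definitions used by the context rule engine, with first-match resolution for
overlapping intervals.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import DataParseError, SchemaError, ValidationError


class _Sentinel:
    """Unique, identity-compared sentinel value."""

    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return self._name

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


#: Marker for a missing cell value (``?`` on disk).  Never imputed.
MISSING = _Sentinel("MISSING")

#: Returned by :func:`discretize` when no band predicate holds.
UNBANDED = _Sentinel("UNBANDED")


@dataclass(frozen=True)
class AttributeSpec:
    """Description of a single column.

    ``numeric_range`` and ``integer_valued`` are optional annotations used by
    the synthetic data generator; they play no role in parsing or matching.
    """

    name: str
    kind: str  # "numeric" | "categorical"
    categories: tuple[str, ...] | None = None
    description: str = ""
    numeric_range: tuple[float, float] | None = None
    integer_valued: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValidationError(f"attribute {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise ValidationError(
                    f"attribute {self.name!r}: categorical spec needs >=1 category"
                )
            object.__setattr__(self, "categories", tuple(str(c) for c in self.categories))
        elif self.categories is not None:
            raise ValidationError(f"attribute {self.name!r}: numeric spec cannot have categories")

    @property
    def is_numeric(self) -> bool:
        return self.kind == "numeric"


@dataclass(frozen=True)
class DatasetSchema:
    """Ordered predictor attributes plus one categorical class attribute."""

    attributes: tuple[AttributeSpec, ...]
    class_attribute: AttributeSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names in schema")
        if self.class_attribute.name in names:
            raise SchemaError(
                f"class attribute {self.class_attribute.name!r} also listed as predictor"
            )
        if self.class_attribute.kind != "categorical":
            raise SchemaError("class attribute must be categorical")

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.attributes)

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise SchemaError(f"unknown attribute {name!r}")

    def has_attribute(self, name: str) -> bool:
        return any(a.name == name for a in self.attributes)


@dataclass
class Instance:
    """One data row: a value per predictor (keyed by name) and an optional label."""

    values: dict[str, object]
    label: str | None = None

    def value(self, name: str) -> object:
        try:
            return self.values[name]
        except KeyError:
            raise SchemaError(f"instance has no attribute {name!r}") from None


@dataclass
class Dataset:
    """A schema plus conforming instances."""

    schema: DatasetSchema
    instances: list[Instance] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self) -> Iterator[Instance]:
        return iter(self.instances)

    def labels(self) -> list[str | None]:
        return [inst.label for inst in self.instances]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for inst in self.instances:
            if inst.label is not None:
                counts[inst.label] = counts.get(inst.label, 0) + 1
        return counts

    def subset(self, indices: Iterable[int]) -> "Dataset":
        rows = self.instances
        return Dataset(self.schema, [rows[i] for i in indices])

    def validate(self) -> None:
        """Raise :class:`ValidationError` on the first schema violation."""
        names = set(self.schema.predictor_names)
        class_cats = set(self.schema.class_attribute.categories or ())
        for i, inst in enumerate(self.instances):
            if set(inst.values) != names:
                raise ValidationError(f"row {i}: attribute set does not match schema")
            for spec in self.schema.attributes:
                v = inst.values[spec.name]
                if v is MISSING:
                    continue
                if spec.is_numeric:
                    if not isinstance(v, (int, float)):
                        raise ValidationError(f"row {i}, column {spec.name!r}: non-numeric value {v!r}")
                elif str(v) not in spec.categories:
                    raise ValidationError(
                        f"row {i}, column {spec.name!r}: value {v!r} not in declared categories"
                    )
            if inst.label is not None and inst.label not in class_cats:
                raise ValidationError(f"row {i}: label {inst.label!r} not a declared class")


def _normalize_token(token: str, categories: Sequence[str]) -> str:
    """Map float-ish tokens like '6.0' onto the declared category '6'."""
    if token in categories:
        return token
    try:
        f = float(token)
    except ValueError:
        return token
    if f == int(f) and str(int(f)) in categories:
        return str(int(f))
    return token


def _parse_cell(token: str, spec: AttributeSpec, row: int) -> object:
    token = token.strip()
    if token == "?" or token == "":
        return MISSING
    if spec.is_numeric:
        try:
            return float(token)
        except ValueError:
            raise DataParseError(
                f"row {row}, column {spec.name!r}: cannot parse numeric cell {token!r}"
            ) from None
    return _normalize_token(token, spec.categories)


def read_csv_dataset(path_or_file, schema: DatasetSchema) -> Dataset:
    """Read a header-bearing CSV into a :class:`Dataset`.

    The header must contain every predictor column (order-insensitive); the
    class column is optional — absent means unlabeled data.  ``?`` and empty
    cells become :data:`MISSING`.
    """
    if hasattr(path_or_file, "read"):
        return _read_csv(path_or_file, schema)
    with open(path_or_file, newline="") as fh:
        return _read_csv(fh, schema)


def _read_csv(fh, schema: DatasetSchema) -> Dataset:
    reader = csv.reader(fh)
    try:
        header = next(reader)
    except StopIteration:
        raise DataParseError("empty file: no header row") from None
    header = [h.strip() for h in header]
    wanted = set(schema.predictor_names) | {schema.class_attribute.name}
    extra = [h for h in header if h not in wanted]
    if extra:
        raise SchemaError(f"unexpected column(s) {extra!r}")
    missing_cols = [n for n in schema.predictor_names if n not in header]
    if missing_cols:
        raise SchemaError(f"missing column(s) {missing_cols!r}")
    col_index = {h: i for i, h in enumerate(header)}
    class_col = col_index.get(schema.class_attribute.name)

    instances: list[Instance] = []
    for rownum, row in enumerate(reader, start=1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise DataParseError(f"row {rownum}: expected {len(header)} cells, got {len(row)}")
        values = {
            spec.name: _parse_cell(row[col_index[spec.name]], spec, rownum)
            for spec in schema.attributes
        }
        label: str | None = None
        if class_col is not None:
            tok = row[class_col].strip()
            if tok and tok != "?":
                label = _normalize_token(tok, schema.class_attribute.categories)
        instances.append(Instance(values, label))
    return Dataset(schema, instances)


def _format_cell(v: object, spec: AttributeSpec) -> str:
    if v is MISSING:
        return "?"
    if spec.is_numeric:
        f = float(v)
        if f == int(f):
            return str(int(f))
        return repr(f)
    return str(v)


def write_csv_dataset(dataset: Dataset, path_or_file) -> None:
    """Write ``dataset`` as a header-bearing CSV (``?`` for missing)."""
    if hasattr(path_or_file, "write"):
        _write_csv(dataset, path_or_file)
    else:
        with open(path_or_file, "w", newline="") as fh:
            _write_csv(dataset, fh)


def _write_csv(dataset: Dataset, fh) -> None:
    schema = dataset.schema
    writer = csv.writer(fh, lineterminator="\n")
    writer.writerow(list(schema.predictor_names) + [schema.class_attribute.name])
    for inst in dataset.instances:
        row = [_format_cell(inst.values[s.name], s) for s in schema.attributes]
        row.append("?" if inst.label is None else inst.label)
        writer.writerow(row)


def dataset_to_csv_text(dataset: Dataset) -> str:
    buf = io.StringIO()
    _write_csv(dataset, buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Cleveland heart-disease layout
# ---------------------------------------------------------------------------

#: Fixed column order of the UCI "processed.cleveland.data" file.
CLEVELAND_COLUMNS = (
    "age", "sex", "cp", "trestbps", "chol", "fbs", "restecg",
    "thalach", "exang", "oldpeak", "slope", "ca", "thal", "num",
)


def cleveland_schema() -> DatasetSchema:
    """Schema of the 13-predictor Cleveland heart-disease layout.

    The class is binary: ``0`` healthy, ``1`` presence of disease (the raw
    multi-level class is collapsed by :func:`load_cleveland`).  The
    ``exang`` column is sometimes mislabeled as a heart-rate measure in dataset
    descriptions; the standard meaning (exercise-induced angina, 0/1) is used.
    """
    return DatasetSchema(
        attributes=(
            AttributeSpec("age", "numeric", description="age in years",
                          numeric_range=(29, 77), integer_valued=True),
            AttributeSpec("sex", "categorical", ("0", "1"), "1=male, 0=female"),
            AttributeSpec("cp", "categorical", ("1", "2", "3", "4"),
                          "chest pain type: 1 typical angina, 2 atypical, 3 non-anginal, 4 asymptomatic"),
            AttributeSpec("trestbps", "numeric", description="resting blood pressure (mmHg)",
                          numeric_range=(94, 200), integer_valued=True),
            AttributeSpec("chol", "numeric", description="serum cholesterol (mg/dl)",
                          numeric_range=(126, 564), integer_valued=True),
            AttributeSpec("fbs", "categorical", ("0", "1"), "fasting blood sugar > 120 mg/dl"),
            AttributeSpec("restecg", "categorical", ("0", "1", "2"), "resting ECG result"),
            AttributeSpec("thalach", "numeric", description="max heart rate achieved",
                          numeric_range=(71, 202), integer_valued=True),
            AttributeSpec("exang", "categorical", ("0", "1"), "exercise-induced angina"),
            AttributeSpec("oldpeak", "numeric",
                          description="ST depression induced by exercise relative to rest",
                          numeric_range=(0.0, 6.2)),
            AttributeSpec("slope", "categorical", ("1", "2", "3"), "slope of peak exercise ST segment"),
            AttributeSpec("ca", "numeric", description="major vessels colored by fluoroscopy (0-3)",
                          numeric_range=(0, 3), integer_valued=True),
            AttributeSpec("thal", "categorical", ("3", "6", "7"),
                          "3 normal, 6 fixed defect, 7 reversible defect"),
        ),
        class_attribute=AttributeSpec("num", "categorical", ("0", "1"),
                                      "0 healthy, 1 presence of heart disease"),
    )


def load_cleveland(path_or_file) -> Dataset:
    """Load a Cleveland heart-disease file (headerless UCI layout or CSV with header).

    Raw class values > 0 collapse to ``1``; missing markers are preserved.
    """
    if hasattr(path_or_file, "read"):
        text = path_or_file.read()
    else:
        with open(path_or_file) as fh:
            text = fh.read()
    schema = cleveland_schema()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    has_header = any(tok.strip() in CLEVELAND_COLUMNS for tok in first.split(","))
    if has_header:
        ds = read_csv_dataset(io.StringIO(text), schema)
    else:
        ds = _read_headerless_cleveland(text, schema)
    for inst in ds.instances:
        if inst.label is not None and inst.label not in ("0", "1"):
            try:
                raw = float(inst.label)
            except ValueError:
                raise DataParseError(f"unparseable class value {inst.label!r}") from None
            inst.label = "1" if raw > 0 else "0"
    ds.validate()
    return ds


def _read_headerless_cleveland(text: str, schema: DatasetSchema) -> Dataset:
    instances: list[Instance] = []
    for rownum, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        cells = [c.strip() for c in line.split(",")]
        if len(cells) != len(CLEVELAND_COLUMNS):
            raise SchemaError(
                f"row {rownum}: expected {len(CLEVELAND_COLUMNS)} columns, got {len(cells)}"
            )
        values = {
            spec.name: _parse_cell(cells[i], spec, rownum)
            for i, spec in zip(range(len(CLEVELAND_COLUMNS) - 1), schema.attributes)
        }
        tok = cells[-1]
        label = None if tok in ("?", "") else _normalize_token(tok, ("0", "1", "2", "3", "4"))
        instances.append(Instance(values, label))
    return Dataset(schema, instances)


# ---------------------------------------------------------------------------
# Clinical band table (first-match discretization)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Band:
    """One band-table row: a label plus a predicate on the raw value.

    ``op`` is one of ``lt gt le ge eq between``; intervals are closed and may
    overlap — resolution is strictly first-match in declared order.
    """

    label: str
    op: str
    lo: float
    hi: float | None = None

    def holds(self, x: float) -> bool:
        if self.op == "lt":
            return x < self.lo
        if self.op == "gt":
            return x > self.lo
        if self.op == "le":
            return x <= self.lo
        if self.op == "ge":
            return x >= self.lo
        if self.op == "eq":
            return x == self.lo
        if self.op == "between":
            return self.lo <= x <= self.hi
        raise ValueError(f"unknown band op {self.op!r}")


#: Ordered band definitions, kept exactly in declared order (bands overlap;
#: first match wins).
BAND_TABLE: dict[str, tuple[Band, ...]] = {
    "chest_pain": (
        Band("Typical angina", "eq", 1),
        Band("Atypical angina", "eq", 2),
        Band("Nonangina", "eq", 3),
        Band("Asymptomatic", "eq", 4),
    ),
    "cholesterol": (
        Band("Lower", "lt", 197),
        Band("Medium", "between", 188, 250),
        Band("Higher", "between", 217, 307),
        Band("Very higher", "gt", 281),
    ),
    "bp": (
        Band("Lower", "lt", 134),
        Band("Medium", "between", 124, 153),
        Band("Higher", "between", 142, 172),
        Band("Very higher", "gt", 154),
    ),
    "blood_sugar": (
        Band("No", "lt", 120),
        Band("Yes", "ge", 120),
    ),
    "ecg": (
        Band("Normal", "lt", 0.4),
        Band("Abnormal", "between", 0.4, 1.8),
        Band("Hypertrophy", "gt", 1.8),
    ),
    "thallium": (
        Band("Normal", "eq", 3),
        Band("Fixed defect", "eq", 6),
        Band("Reversible defect", "eq", 7),
    ),
    "age": (
        Band("Younger", "lt", 35),
        Band("Middle", "between", 35, 45),
        Band("Older", "between", 40, 58),
        Band("Very older", "gt", 58),
    ),
    "gender": (
        Band("Male", "eq", 1),
        Band("Female", "eq", 0),
    ),
    "smoking": (
        Band("Lower", "le", 10),
        Band("Higher", "gt", 10),
    ),
    "drinking": (
        Band("No", "eq", 0),
        Band("Yes", "eq", 1),
    ),
    "family_history": (
        Band("No", "lt", 1),
        Band("Yes", "ge", 1),
    ),
    "medical_records": (
        Band("No", "lt", 1),
        Band("Yes", "ge", 1),
    ),
}


def discretize(attribute: str, raw_value) -> object:
    """Return the first band label whose predicate holds for ``raw_value``.

    Returns :data:`UNBANDED` when no band matches (including MISSING input);
    never raises for in-table attributes.  Unknown attributes raise
    :class:`LookupError`.
    """
    if attribute not in BAND_TABLE:
        raise LookupError(f"no bands defined for attribute {attribute!r}")
    if raw_value is MISSING or raw_value is None:
        return UNBANDED
    try:
        x = float(raw_value)
    except (TypeError, ValueError):
        return UNBANDED
    for band in BAND_TABLE[attribute]:
        if band.holds(x):
            return band.label
    return UNBANDED
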
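"""OMOP CDM v5.4 table schemas and row types for the five vital-signs tables.

Two key conventions coexist:

* the **logical** model, where primary/foreign key columns still hold
  string source values (FHIR business identifiers) awaiting surrogate-key
  resolution, and
* the **physical** model, where the same columns hold positive integers and
  business identifiers have been stripped (de-identified).

The Measurement table ships in two variants: the 22-column working model
(CDM v5.4 without ``visit_detail_id``, the variant whose transformed/total
arithmetic the coverage report is built on) and the full 23-column CDM v5.4
layout.  CSV I/O uses RFC-4180 quoting, ISO-8601 dates/times and empty
strings for NULL.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields as dc_fields
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Optional, Union

from fhiromop.errors import FhirOmopError

__all__ = [
    "Kind",
    "ColumnSpec",
    "TableSchema",
    "MeasurementRow",
    "PersonRow",
    "VisitOccurrenceRow",
    "ProviderRow",
    "CareSiteRow",
    "OmopRowSet",
    "TABLE_NAMES",
    "ROW_TYPES",
    "PAPER_VARIANT",
    "CDM54_FULL",
    "table_schema",
    "write_table",
    "read_table",
]

PAPER_VARIANT = "paper-22col"
CDM54_FULL = "cdm54-full"

TABLE_NAMES = ("care_site", "provider", "person", "visit_occurrence", "measurement")


class Kind(str, Enum):
    """Value kind of an OMOP column, driving CSV parsing and key handling."""

    INTEGER = "integer"
    DECIMAL = "decimal"
    DATE = "date"
    DATETIME = "datetime"
    TIME = "time"
    STRING = "string"
    CONCEPT_ID = "concept-id"
    KEY = "key"


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: Kind
    mandatory: bool = False


@dataclass(frozen=True)
class TableSchema:
    table_name: str
    columns: tuple[ColumnSpec, ...]
    variant: str = PAPER_VARIANT

    def __post_init__(self) -> None:
        names = [c.name for c in self.columns]
        if len(names) != len(set(names)):
            raise FhirOmopError(f"duplicate column names in schema {self.table_name}")

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @property
    def mandatory_columns(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.mandatory)

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise FhirOmopError(f"{self.table_name} has no column {name!r}")


Key = Union[int, str]  # int in the physical model, source-value string in the logical one


@dataclass
class CareSiteRow:
    care_site_id: Optional[Key] = None
    care_site_name: Optional[str] = None
    place_of_service_concept_id: Optional[int] = None
    location_id: Optional[Key] = None
    care_site_source_value: Optional[str] = None
    place_of_service_source_value: Optional[str] = None


@dataclass
class ProviderRow:
    provider_id: Optional[Key] = None
    provider_name: Optional[str] = None
    npi: Optional[str] = None
    dea: Optional[str] = None
    specialty_concept_id: Optional[int] = None
    care_site_id: Optional[Key] = None
    year_of_birth: Optional[int] = None
    gender_concept_id: Optional[int] = None
    provider_source_value: Optional[str] = None
    specialty_source_value: Optional[str] = None
    specialty_source_concept_id: Optional[int] = None
    gender_source_value: Optional[str] = None
    gender_source_concept_id: Optional[int] = None


@dataclass
class PersonRow:
    person_id: Optional[Key] = None
    gender_concept_id: Optional[int] = None
    year_of_birth: Optional[int] = None
    month_of_birth: Optional[int] = None
    day_of_birth: Optional[int] = None
    birth_datetime: Optional[str] = None
    race_concept_id: Optional[int] = None
    ethnicity_concept_id: Optional[int] = None
    location_id: Optional[Key] = None
    provider_id: Optional[Key] = None
    care_site_id: Optional[Key] = None
    person_source_value: Optional[str] = None
    gender_source_value: Optional[str] = None
    gender_source_concept_id: Optional[int] = None
    race_source_value: Optional[str] = None
    race_source_concept_id: Optional[int] = None
    ethnicity_source_value: Optional[str] = None
    ethnicity_source_concept_id: Optional[int] = None


@dataclass
class VisitOccurrenceRow:
    visit_occurrence_id: Optional[Key] = None
    person_id: Optional[Key] = None
    visit_concept_id: Optional[int] = None
    visit_start_date: Optional[str] = None
    visit_start_datetime: Optional[str] = None
    visit_end_date: Optional[str] = None
    visit_end_datetime: Optional[str] = None
    visit_type_concept_id: Optional[int] = None
    provider_id: Optional[Key] = None
    care_site_id: Optional[Key] = None
    visit_source_value: Optional[str] = None
    visit_source_concept_id: Optional[int] = None
    admitted_from_concept_id: Optional[int] = None
    admitted_from_source_value: Optional[str] = None
    discharged_to_concept_id: Optional[int] = None
    discharged_to_source_value: Optional[str] = None
    preceding_visit_occurrence_id: Optional[Key] = None


@dataclass
class MeasurementRow:
    measurement_id: Optional[Key] = None
    person_id: Optional[Key] = None
    measurement_concept_id: Optional[int] = None
    measurement_date: Optional[str] = None
    measurement_datetime: Optional[str] = None
    measurement_time: Optional[str] = None
    measurement_type_concept_id: Optional[int] = None
    operator_concept_id: Optional[int] = None
    value_as_number: Optional[float] = None
    value_as_concept_id: Optional[int] = None
    unit_concept_id: Optional[int] = None
    range_low: Optional[float] = None
    range_high: Optional[float] = None
    provider_id: Optional[Key] = None
    visit_occurrence_id: Optional[Key] = None
    visit_detail_id: Optional[Key] = None  # excluded from the 22-column variant
    measurement_source_value: Optional[str] = None
    measurement_source_concept_id: Optional[int] = None
    unit_source_value: Optional[str] = None
    unit_source_concept_id: Optional[int] = None
    value_source_value: Optional[str] = None
    measurement_event_id: Optional[Key] = None
    meas_event_field_concept_id: Optional[int] = None


ROW_TYPES = {
    "care_site": CareSiteRow,
    "provider": ProviderRow,
    "person": PersonRow,
    "visit_occurrence": VisitOccurrenceRow,
    "measurement": MeasurementRow,
}

_C = ColumnSpec
_K = Kind

_CARE_SITE_COLUMNS = (
    _C("care_site_id", _K.KEY, mandatory=True),
    _C("care_site_name", _K.STRING),
    _C("place_of_service_concept_id", _K.CONCEPT_ID),
    _C("location_id", _K.KEY),
    _C("care_site_source_value", _K.STRING),
    _C("place_of_service_source_value", _K.STRING),
)

_PROVIDER_COLUMNS = (
    _C("provider_id", _K.KEY, mandatory=True),
    _C("provider_name", _K.STRING),
    _C("npi", _K.STRING),
    _C("dea", _K.STRING),
    _C("specialty_concept_id", _K.CONCEPT_ID),
    _C("care_site_id", _K.KEY),
    _C("year_of_birth", _K.INTEGER),
    _C("gender_concept_id", _K.CONCEPT_ID),
    _C("provider_source_value", _K.STRING),
    _C("specialty_source_value", _K.STRING),
    _C("specialty_source_concept_id", _K.CONCEPT_ID),
    _C("gender_source_value", _K.STRING),
    _C("gender_source_concept_id", _K.CONCEPT_ID),
)

_PERSON_COLUMNS = (
    _C("person_id", _K.KEY, mandatory=True),
    _C("gender_concept_id", _K.CONCEPT_ID, mandatory=True),
    _C("year_of_birth", _K.INTEGER, mandatory=True),
    _C("month_of_birth", _K.INTEGER),
    _C("day_of_birth", _K.INTEGER),
    _C("birth_datetime", _K.DATETIME),
    _C("race_concept_id", _K.CONCEPT_ID, mandatory=True),
    _C("ethnicity_concept_id", _K.CONCEPT_ID, mandatory=True),
    _C("location_id", _K.KEY),
    _C("provider_id", _K.KEY),
    _C("care_site_id", _K.KEY),
    _C("person_source_value", _K.STRING),
    _C("gender_source_value", _K.STRING),
    _C("gender_source_concept_id", _K.CONCEPT_ID),
    _C("race_source_value", _K.STRING),
    _C("race_source_concept_id", _K.CONCEPT_ID),
    _C("ethnicity_source_value", _K.STRING),
    _C("ethnicity_source_concept_id", _K.CONCEPT_ID),
)

_VISIT_COLUMNS = (
    _C("visit_occurrence_id", _K.KEY, mandatory=True),
    _C("person_id", _K.KEY, mandatory=True),
    _C("visit_concept_id", _K.CONCEPT_ID, mandatory=True),
    _C("visit_start_date", _K.DATE, mandatory=True),
    _C("visit_start_datetime", _K.DATETIME),
    _C("visit_end_date", _K.DATE, mandatory=True),
    _C("visit_end_datetime", _K.DATETIME),
    _C("visit_type_concept_id", _K.CONCEPT_ID, mandatory=True),
    _C("provider_id", _K.KEY),
    _C("care_site_id", _K.KEY),
    _C("visit_source_value", _K.STRING),
    _C("visit_source_concept_id", _K.CONCEPT_ID),
    _C("admitted_from_concept_id", _K.CONCEPT_ID),
    _C("admitted_from_source_value", _K.STRING),
    _C("discharged_to_concept_id", _K.CONCEPT_ID),
    _C("discharged_to_source_value", _K.STRING),
    _C("preceding_visit_occurrence_id", _K.KEY),
)

_MEASUREMENT_COLUMNS_FULL = (
    _C("measurement_id", _K.KEY, mandatory=True),
    _C("person_id", _K.KEY, mandatory=True),
    _C("measurement_concept_id", _K.CONCEPT_ID, mandatory=True),
    _C("measurement_date", _K.DATE, mandatory=True),
    _C("measurement_datetime", _K.DATETIME),
    _C("measurement_time", _K.TIME),
    _C("measurement_type_concept_id", _K.CONCEPT_ID, mandatory=True),
    _C("operator_concept_id", _K.CONCEPT_ID),
    _C("value_as_number", _K.DECIMAL),
    _C("value_as_concept_id", _K.CONCEPT_ID),
    _C("unit_concept_id", _K.CONCEPT_ID),
    _C("range_low", _K.DECIMAL),
    _C("range_high", _K.DECIMAL),
    _C("provider_id", _K.KEY),
    _C("visit_occurrence_id", _K.KEY),
    _C("visit_detail_id", _K.KEY),
    _C("measurement_source_value", _K.STRING),
    _C("measurement_source_concept_id", _K.CONCEPT_ID),
    _C("unit_source_value", _K.STRING),
    _C("unit_source_concept_id", _K.CONCEPT_ID),
    _C("value_source_value", _K.STRING),
    _C("measurement_event_id", _K.KEY),
    _C("meas_event_field_concept_id", _K.CONCEPT_ID),
)

_MEASUREMENT_COLUMNS_22 = tuple(
    c for c in _MEASUREMENT_COLUMNS_FULL if c.name != "visit_detail_id"
)

_SCHEMAS: dict[tuple[str, str], TableSchema] = {}
for _variant in (PAPER_VARIANT, CDM54_FULL):
    _SCHEMAS[("care_site", _variant)] = TableSchema("care_site", _CARE_SITE_COLUMNS, _variant)
    _SCHEMAS[("provider", _variant)] = TableSchema("provider", _PROVIDER_COLUMNS, _variant)
    _SCHEMAS[("person", _variant)] = TableSchema("person", _PERSON_COLUMNS, _variant)
    _SCHEMAS[("visit_occurrence", _variant)] = TableSchema(
        "visit_occurrence", _VISIT_COLUMNS, _variant
    )
_SCHEMAS[("measurement", PAPER_VARIANT)] = TableSchema(
    "measurement", _MEASUREMENT_COLUMNS_22, PAPER_VARIANT
)
_SCHEMAS[("measurement", CDM54_FULL)] = TableSchema(
    "measurement", _MEASUREMENT_COLUMNS_FULL, CDM54_FULL
)


def table_schema(table_name: str, variant: str = PAPER_VARIANT) -> TableSchema:
    """Return the fixed schema for one of the five supported tables.

    ``variant`` selects the Measurement layout: the 22-column working model
    or the full 23-column CDM v5.4 one (the other four tables are identical
    in both variants).
    """
    try:
        return _SCHEMAS[(table_name, variant)]
    except KeyError:
        if variant not in (PAPER_VARIANT, CDM54_FULL):
            raise FhirOmopError(f"unknown schema variant: {variant!r}") from None
        raise FhirOmopError(
            f"unknown table {table_name!r}; expected one of {', '.join(TABLE_NAMES)}"
        ) from None


@dataclass
class OmopRowSet:
    """Per-table row lists plus a provenance marker (logical vs physical keys)."""

    care_site: list[CareSiteRow] = field(default_factory=list)
    provider: list[ProviderRow] = field(default_factory=list)
    person: list[PersonRow] = field(default_factory=list)
    visit_occurrence: list[VisitOccurrenceRow] = field(default_factory=list)
    measurement: list[MeasurementRow] = field(default_factory=list)
    provenance: str = "logical"

    def rows(self, table_name: str) -> list:
        if table_name not in TABLE_NAMES:
            raise FhirOmopError(f"unknown table {table_name!r}")
        return getattr(self, table_name)

    def counts(self) -> dict[str, int]:
        return {name: len(self.rows(name)) for name in TABLE_NAMES}


def _format_value(value: object, col: ColumnSpec) -> str:
    if value is None:
        return ""
    if col.kind == Kind.DECIMAL and isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def _parse_value(text: str, col: ColumnSpec) -> object:
    if text == "":
        return None
    if col.kind == Kind.DECIMAL:
        return float(text)
    if col.kind in (Kind.INTEGER, Kind.CONCEPT_ID):
        return int(text)
    if col.kind == Kind.KEY:
        # physical keys are integers; logical key columns carry source strings
        return int(text) if text.isdigit() else text
    return text


def write_table(rows: Iterable, schema: TableSchema, sink: Union[str, Path, IO[str], None] = None) -> str:
    """Write rows as CSV (header = schema column order); returns the CSV text.

    ``sink`` may be a path or an open text file; when omitted the CSV is only
    returned.  Raises on rows whose fields do not cover the schema, naming
    the missing column.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(schema.column_names)
    for row in rows:
        row_fields = {f.name for f in dc_fields(row)}
        values = []
        for col in schema.columns:
            if col.name not in row_fields:
                raise FhirOmopError(
                    f"row {type(row).__name__} lacks column {col.name!r} "
                    f"required by schema {schema.table_name}"
                )
            values.append(_format_value(getattr(row, col.name), col))
        writer.writerow(values)
    text = buf.getvalue()
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    elif sink is not None:
        sink.write(text)
    return text


def read_table(source: Union[str, Path, IO[str]], schema: TableSchema) -> list:
    """Read a CSV produced by :func:`write_table` back into typed rows.

    ``source`` is a path, an open text file, or CSV text itself (anything
    containing a newline is treated as text).  The header must equal the
    schema's column order.  ``read_table(write_table(rows)) == rows``.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, str):
        text = source
    elif isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    else:
        text = source.read()
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise FhirOmopError(f"empty CSV for table {schema.table_name}") from None
    if tuple(header) != schema.column_names:
        raise FhirOmopError(
            f"CSV header does not match schema {schema.table_name} "
            f"({schema.variant}): {header!r}"
        )
    row_type = ROW_TYPES[schema.table_name]
    rows = []
    for record in reader:
        if not record:
            continue
        if len(record) != len(schema.columns):
            raise FhirOmopError(
                f"row has {len(record)} fields, schema {schema.table_name} expects "
                f"{len(schema.columns)}"
            )
        kwargs = {
            col.name: _parse_value(cell, col) for col, cell in zip(schema.columns, record)
        }
        rows.append(row_type(**kwargs))
    return rows
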
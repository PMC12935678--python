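"""Declarative mapping specification and column-level completeness statistics.

Coverage is computed from the *declared* mapping specification — which
columns the rule set is able to populate and how (direct copy, indirect via
terminology/key resolution, constant) — not from data presence in any
particular rowset; that matches a column-level analysis of the rules
themselves.  :func:`audit_rowset` separately checks that an actual
transformed rowset honors the declaration.

Rounding is half-up to integer percent, the only convention consistent with
all of {5/6: 83, 7/13: 54, 11/18: 61, 15/17: 88, 18/22: 82, 56/76: 74}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional

from fhiromop.errors import FhirOmopError
from fhiromop.omop_model import OmopRowSet, TABLE_NAMES, TableSchema, table_schema

__all__ = [
    "KINDS",
    "TRANSFORMED_KINDS",
    "MappingSpec",
    "CoverageRow",
    "Discrepancy",
    "coverage_report",
    "overall_coverage",
    "audit_rowset",
    "default_mapping_spec",
]

KINDS = frozenset({"direct", "indirect", "constant", "none"})
TRANSFORMED_KINDS = frozenset({"direct", "indirect", "constant"})

#: Columns populated only under a data-dependent condition (a comparator on
#: the source Quantity); exempt from the audit's "unexercised" check.
DEFAULT_CONDITIONAL = frozenset({("measurement", "operator_concept_id")})


@dataclass
class MappingSpec:
    """Per-table classification of every schema column into a mapping kind."""

    tables: dict[str, dict[str, str]] = field(default_factory=dict)

    def table(self, table_name: str) -> dict[str, str]:
        try:
            return self.tables[table_name]
        except KeyError:
            raise FhirOmopError(f"mapping spec has no table {table_name!r}") from None

    def transformed_columns(self, table_name: str) -> frozenset[str]:
        return frozenset(
            column
            for column, kind in self.table(table_name).items()
            if kind in TRANSFORMED_KINDS
        )


@dataclass(frozen=True)
class CoverageRow:
    table_name: str
    transformed: int
    total: int
    untransformed_mandatory: int
    percentage: int


@dataclass(frozen=True)
class Discrepancy:
    table_name: str
    column: str
    kind: str  # "unexpected" (populated outside spec) | "unexercised" (spec'd, never populated)


def _round_half_up_percent(numerator: int, denominator: int) -> int:
    value = Fraction(numerator * 100, denominator) + Fraction(1, 2)
    return value.numerator // value.denominator


def coverage_report(spec: MappingSpec, schema: TableSchema) -> CoverageRow:
    """Completeness statistics for one table under a mapping specification.

    Transformed = columns classified direct/indirect/constant;
    untransformed-mandatory = mandatory columns classified none.  Raises when
    the spec leaves a schema column unclassified or names an unknown one.
    """
    classification = spec.table(schema.table_name)
    unknown = set(classification) - set(schema.column_names)
    if unknown:
        raise FhirOmopError(
            f"{schema.table_name}: spec classifies unknown column(s) {sorted(unknown)}"
        )
    missing = set(schema.column_names) - set(classification)
    if missing:
        raise FhirOmopError(
            f"{schema.table_name}: spec leaves column(s) {sorted(missing)} unclassified"
        )
    bad_kinds = {k for k in classification.values() if k not in KINDS}
    if bad_kinds:
        raise FhirOmopError(f"{schema.table_name}: unknown mapping kind(s) {sorted(bad_kinds)}")
    transformed = sum(1 for kind in classification.values() if kind in TRANSFORMED_KINDS)
    untransformed_mandatory = sum(
        1 for col in schema.columns if col.mandatory and classification[col.name] == "none"
    )
    return CoverageRow(
        table_name=schema.table_name,
        transformed=transformed,
        total=len(schema.columns),
        untransformed_mandatory=untransformed_mandatory,
        percentage=_round_half_up_percent(transformed, len(schema.columns)),
    )


def overall_coverage(rows: Iterable[CoverageRow]) -> int:
    """Pooled percentage over tables: round(sum transformed / sum total)."""
    rows = list(rows)
    if not rows:
        raise FhirOmopError("overall coverage of an empty report is undefined")
    transformed = sum(r.transformed for r in rows)
    total = sum(r.total for r in rows)
    return _round_half_up_percent(transformed, total)


def audit_rowset(
    rowset: OmopRowSet,
    spec: MappingSpec,
    variant: str = "paper-22col",
    conditional: frozenset[tuple[str, str]] = DEFAULT_CONDITIONAL,
) -> list[Discrepancy]:
    """Check that a transformed rowset honors the mapping specification.

    Reports columns populated outside the spec's transformed set
    (``unexpected``) and spec'd columns never populated in any row
    (``unexercised``, excluding declared conditional columns).  An empty
    report means the implementation and the declaration agree on the given
    data.
    """
    discrepancies: list[Discrepancy] = []
    for table_name in TABLE_NAMES:
        schema = table_schema(table_name, variant)
        declared = spec.transformed_columns(table_name)
        populated: set[str] = set()
        for row in rowset.rows(table_name):
            populated.update(
                col.name for col in schema.columns if getattr(row, col.name) is not None
            )
        for column in sorted(populated - declared):
            discrepancies.append(Discrepancy(table_name, column, "unexpected"))
        unexercised = declared - populated
        for column in sorted(unexercised):
            if (table_name, column) in conditional:
                continue
            discrepancies.append(Discrepancy(table_name, column, "unexercised"))
    return discrepancies


def default_mapping_spec() -> MappingSpec:
    """The shipped mapping specification for the default rule set.

    The transformed sets are the package's reconstruction of what the rules
    populate per table (Care Site 5, Provider 7, Person 11, Visit Occurrence
    15, Measurement 18); the four mandatory columns classified ``none`` are
    race and ethnicity (Person), visit_type_concept_id and
    measurement_type_concept_id — record-origin and demographic data absent
    from base FHIR resources.
    """
    return MappingSpec(
        tables={
            "care_site": {
                "care_site_id": "indirect",
                "care_site_name": "direct",
                "place_of_service_concept_id": "indirect",
                "location_id": "none",
                "care_site_source_value": "indirect",
                "place_of_service_source_value": "direct",
            },
            "provider": {
                "provider_id": "indirect",
                "provider_name": "direct",
                "npi": "none",
                "dea": "none",
                "specialty_concept_id": "none",
                "care_site_id": "none",
                "year_of_birth": "indirect",
                "gender_concept_id": "indirect",
                "provider_source_value": "indirect",
                "specialty_source_value": "none",
                "specialty_source_concept_id": "none",
                "gender_source_value": "direct",
                "gender_source_concept_id": "indirect",
            },
            "person": {
                "person_id": "indirect",
                "gender_concept_id": "indirect",
                "year_of_birth": "indirect",
                "month_of_birth": "indirect",
                "day_of_birth": "indirect",
                "birth_datetime": "indirect",
                "race_concept_id": "none",
                "ethnicity_concept_id": "none",
                "location_id": "none",
                "provider_id": "indirect",
                "care_site_id": "indirect",
                "person_source_value": "indirect",
                "gender_source_value": "direct",
                "gender_source_concept_id": "indirect",
                "race_source_value": "none",
                "race_source_concept_id": "none",
                "ethnicity_source_value": "none",
                "ethnicity_source_concept_id": "none",
            },
            "visit_occurrence": {
                "visit_occurrence_id": "indirect",
                "person_id": "indirect",
                "visit_concept_id": "indirect",
                "visit_start_date": "indirect",
                "visit_start_datetime": "direct",
                "visit_end_date": "indirect",
                "visit_end_datetime": "direct",
                "visit_type_concept_id": "none",
                "provider_id": "indirect",
                "care_site_id": "indirect",
                "visit_source_value": "indirect",
                "visit_source_concept_id": "none",
                "admitted_from_concept_id": "indirect",
                "admitted_from_source_value": "direct",
                "discharged_to_concept_id": "indirect",
                "discharged_to_source_value": "direct",
                "preceding_visit_occurrence_id": "indirect",
            },
            "measurement": {
                "measurement_id": "indirect",
                "person_id": "indirect",
                "measurement_concept_id": "indirect",
                "measurement_date": "indirect",
                "measurement_datetime": "indirect",
                "measurement_time": "indirect",
                "measurement_type_concept_id": "none",
                "operator_concept_id": "indirect",
                "value_as_number": "direct",
                "value_as_concept_id": "none",
                "unit_concept_id": "indirect",
                "range_low": "direct",
                "range_high": "direct",
                "provider_id": "indirect",
                "visit_occurrence_id": "indirect",
                "measurement_source_value": "indirect",
                "measurement_source_concept_id": "none",
                "unit_source_value": "direct",
                "unit_source_concept_id": "none",
                "value_source_value": "direct",
                "measurement_event_id": "indirect",
                "meas_event_field_concept_id": "constant",
            },
        }
    )


def full_report(
    spec: Optional[MappingSpec] = None, variant: str = "paper-22col"
) -> tuple[list[CoverageRow], int]:
    """Coverage rows for all five tables plus the pooled overall percentage."""
    spec = spec or default_mapping_spec()
    rows = [coverage_report(spec, table_schema(name, variant)) for name in TABLE_NAMES]
    return rows, overall_coverage(rows)
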
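"""De-identification-aware key management: link tables and surrogate keys.

FHIR business identifiers (strings) cannot serve as OMOP primary keys — they
would defeat de-identification and naive string-to-integer hashing can
collide.  Instead, each table owns a link table mapping identifier strings to
sequential surrogate integers; the link tables live *outside* the CDM output
(the two-parallel-databases pattern) and the finalized physical rows carry
only integers, with identifier-bearing ``*_source_value`` columns cleared.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

from fhiromop.errors import DanglingReferenceError, FhirOmopError
from fhiromop.fhir_model import ResourceReference
from fhiromop.omop_model import OmopRowSet, TABLE_NAMES

__all__ = [
    "LinkTable",
    "LinkRegistry",
    "RESOURCE_TABLE",
    "business_identifier",
    "resolve_logical_reference",
    "assign_surrogate_keys",
    "finalize_physical",
]

#: FHIR resource type -> OMOP table it feeds.
RESOURCE_TABLE = {
    "Patient": "person",
    "Encounter": "visit_occurrence",
    "Practitioner": "provider",
    "Organization": "care_site",
    "Observation": "measurement",
}


@dataclass
class LinkTable:
    """source-value string -> surrogate integer key; injective both ways.

    Keys are sequential positive integers starting at ``offset + 1``; given
    identical insertion order the mapping is identical across runs.
    """

    table_name: str
    offset: int = 0
    entries: dict[str, int] = field(default_factory=dict)

    def assign(self, source_value: str) -> int:
        key = self.entries.get(source_value)
        if key is None:
            key = self.offset + len(self.entries) + 1
            self.entries[source_value] = key
        return key

    def lookup(self, source_value: str) -> Optional[int]:
        return self.entries.get(source_value)

    def to_csv(self, sink: Union[str, Path, None] = None) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["source_value", "key"])
        for value, key in self.entries.items():
            writer.writerow([value, key])
        text = buf.getvalue()
        if sink is not None:
            Path(sink).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_csv(cls, source: Union[str, Path], table_name: str) -> "LinkTable":
        text = Path(source).read_text(encoding="utf-8")
        reader = csv.reader(io.StringIO(text))
        header = next(reader, None)
        if header != ["source_value", "key"]:
            raise FhirOmopError(f"not a link-table CSV: header {header!r}")
        table = cls(table_name=table_name)
        for value, key in (r for r in reader if r):
            table.entries[value] = int(key)
        return table


@dataclass
class LinkRegistry:
    """One LinkTable per OMOP table; tables are keyed independently."""

    tables: dict[str, LinkTable] = field(default_factory=dict)
    offset: int = 0

    def table(self, table_name: str) -> LinkTable:
        if table_name not in TABLE_NAMES:
            raise FhirOmopError(f"unknown table {table_name!r}")
        if table_name not in self.tables:
            self.tables[table_name] = LinkTable(table_name=table_name, offset=self.offset)
        return self.tables[table_name]

    def write(self, directory: Union[str, Path]) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, table in self.tables.items():
            path = directory / f"{name}_links.csv"
            table.to_csv(path)
            written.append(path)
        return written

    @classmethod
    def read(cls, directory: Union[str, Path]) -> "LinkRegistry":
        registry = cls()
        for path in sorted(Path(directory).glob("*_links.csv")):
            name = path.name[: -len("_links.csv")]
            registry.tables[name] = LinkTable.from_csv(path, name)
        return registry


def business_identifier(resource) -> str:
    """Stable identifier of a resource for cross-standard linkage.

    First identifier's value, system-qualified as ``system|value`` when a
    system is present; falls back to the resource id.  The business
    identifier is preferred because it is stable outside the FHIR server.
    """
    identifiers = getattr(resource, "identifier", None) or []
    for ident in identifiers:
        if ident.value:
            return f"{ident.system}|{ident.value}" if ident.system else ident.value
    rid = getattr(resource, "id", None)
    if rid:
        return rid
    raise FhirOmopError(
        f"{getattr(resource, 'resourceType', type(resource).__name__)} has neither an "
        "identifier nor an id; cannot derive a business identifier"
    )


def resolve_logical_reference(ref: ResourceReference) -> tuple[str, str]:
    """Resolve a resource reference to ``(target-table, source-value)``.

    Literal ``Type/id`` references yield the trailing id; logical
    (identifier-based) references yield the same ``system|value`` dialect as
    :func:`business_identifier`, so both spellings of a reference key the
    same link-table entry.
    """
    if ref is None or ref.is_empty():
        raise FhirOmopError("empty resource reference")
    rtype: Optional[str] = ref.type
    source_value: Optional[str] = None
    if ref.reference:
        if "/" in ref.reference:
            prefix, _, tail = ref.reference.rpartition("/")
            rtype = rtype or prefix.split("/")[-1]
            source_value = tail
        else:
            source_value = ref.reference
    elif ref.identifier is not None and ref.identifier.value:
        source_value = (
            f"{ref.identifier.system}|{ref.identifier.value}"
            if ref.identifier.system
            else ref.identifier.value
        )
    if not source_value:
        raise FhirOmopError(f"reference carries no resolvable value: {ref!r}")
    if not rtype:
        raise FhirOmopError(f"reference has no resource type: {ref!r}")
    table = RESOURCE_TABLE.get(rtype)
    if table is None:
        raise FhirOmopError(f"reference targets unsupported resource type {rtype!r}")
    return table, source_value


def assign_surrogate_keys(
    registry: LinkRegistry, table_name: str, source_values: Iterable[str]
) -> LinkRegistry:
    """Assign sequential surrogate keys; idempotent and duplicate-safe.

    New values get the next integer in insertion order, values already in the
    link table keep their key.  Returns the (mutated) registry for chaining.
    """
    table = registry.table(table_name)
    for value in source_values:
        table.assign(value)
    return registry


# Key-bearing columns per table: column -> link table its values resolve against.
_FK_COLUMNS: dict[str, dict[str, str]] = {
    "care_site": {},
    "provider": {"care_site_id": "care_site"},
    "person": {"provider_id": "provider", "care_site_id": "care_site"},
    "visit_occurrence": {
        "person_id": "person",
        "provider_id": "provider",
        "care_site_id": "care_site",
        "preceding_visit_occurrence_id": "visit_occurrence",
    },
    "measurement": {
        "person_id": "person",
        "provider_id": "provider",
        "visit_occurrence_id": "visit_occurrence",
    },
}

_PK_COLUMN = {
    "care_site": "care_site_id",
    "provider": "provider_id",
    "person": "person_id",
    "visit_occurrence": "visit_occurrence_id",
    "measurement": "measurement_id",
}

#: ``*_source_value`` columns that carry business identifiers in the logical
#: model and are cleared on finalization (identifiers live on in link tables).
_IDENTIFIER_SOURCE_COLUMNS = {
    "care_site": ("care_site_source_value",),
    "provider": ("provider_source_value",),
    "person": ("person_source_value",),
    "visit_occurrence": ("visit_source_value",),
    "measurement": ("measurement_source_value",),
}


def finalize_physical(
    rowset: OmopRowSet,
    registry: Optional[LinkRegistry] = None,
    strict: bool = False,
    clear_source_values: bool = True,
) -> tuple[OmopRowSet, LinkRegistry, list[str]]:
    """Turn a logical rowset into a de-identified physical one.

    Primary keys are assigned per table in row order; foreign keys are then
    resolved against the link tables.  ``measurement_event_id`` is keyed
    through the *measurement* link table (it carries the observation's
    business identifier, so a blood-pressure pair receives one shared group
    key).  Unresolvable foreign keys raise in strict mode and are emptied
    with a warning otherwise.  ``clear_source_values=False`` keeps business
    identifiers in ``*_source_value`` for traceability (non-default).

    Returns ``(physical rowset, registry, warnings)``.
    """
    if rowset.provenance == "physical":
        raise FhirOmopError("rowset is already physical")
    registry = registry if registry is not None else LinkRegistry()
    warnings: list[str] = []

    physical = OmopRowSet(provenance="physical")
    # First pass: assign primary keys so forward references resolve.
    for table_name in TABLE_NAMES:
        link = registry.table(table_name)
        for row in rowset.rows(table_name):
            pk_source = getattr(row, _PK_COLUMN[table_name])
            if pk_source is None:
                raise FhirOmopError(f"{table_name} row lacks a primary-key source value")
            link.assign(str(pk_source))
    # Event keys share the measurement link table (group keys for BP pairs).
    meas_link = registry.table("measurement")
    for row in rowset.measurement:
        if row.measurement_event_id is not None:
            meas_link.assign(str(row.measurement_event_id))

    for table_name in TABLE_NAMES:
        link = registry.table(table_name)
        for row in rowset.rows(table_name):
            new_row = replace(row)
            setattr(
                new_row,
                _PK_COLUMN[table_name],
                link.lookup(str(getattr(row, _PK_COLUMN[table_name]))),
            )
            for column, target_table in _FK_COLUMNS[table_name].items():
                value = getattr(row, column)
                if value is None:
                    continue
                key = registry.table(target_table).lookup(str(value))
                if key is None:
                    message = (
                        f"{table_name}.{column}: dangling reference {value!r} "
                        f"(no {target_table} record)"
                    )
                    if strict:
                        raise DanglingReferenceError(message)
                    warnings.append(message)
                    key = None
                setattr(new_row, column, key)
            if table_name == "measurement" and row.measurement_event_id is not None:
                new_row.measurement_event_id = meas_link.lookup(str(row.measurement_event_id))
            if clear_source_values:
                for column in _IDENTIFIER_SOURCE_COLUMNS[table_name]:
                    setattr(new_row, column, None)
            physical.rows(table_name).append(new_row)
    return physical, registry, warnings
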
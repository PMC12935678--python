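"""FHIR -> OMOP logical-model transformation rules.

Five resource/table rules (Observation->Measurement, Patient->Person,
Encounter->Visit Occurrence, Practitioner->Provider,
Organization->Care Site) plus the two-rule blood-pressure split: a
composite blood-pressure Observation carries systolic and diastolic values
in components, while the Measurement table stores one record per value, so
the resource is pushed through two independent component rules keyed on
LOINC 8480-6 (systolic) and 8462-4 (diastolic).  The resulting pair shares
``measurement_event_id`` (the observation's business identifier) and marks
``meas_event_field_concept_id`` with the standard concept 1147138, meaning
the event key originates from the measurement_id column.

Every rule consumes exactly one resource and emits rows for exactly one
table (the one-input/one-output discipline); :func:`transform_bundle` is
pure orchestration.  Output rows are *logical*: key columns carry business
identifiers until :func:`fhiromop.key_management.finalize_physical` runs.
Unmapped codes leave the concept column empty and log a warning — they never
fail the row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Optional, Union

from fhiromop.concept_maps import ConceptMap, load_shipped_maps, translate
from fhiromop.errors import TransformError
from fhiromop.fhir_model import (
    CodeableConcept,
    FhirBundle,
    FhirEncounter,
    FhirObservation,
    FhirOrganization,
    FhirPatient,
    FhirPractitioner,
    Quantity,
    ResourceReference,
)
from fhiromop.key_management import business_identifier, resolve_logical_reference
from fhiromop.omop_model import (
    CareSiteRow,
    MeasurementRow,
    OmopRowSet,
    PersonRow,
    ProviderRow,
    VisitOccurrenceRow,
)

__all__ = [
    "MEAS_EVENT_FIELD_CONCEPT_ID",
    "SYSTOLIC_RULE",
    "DIASTOLIC_RULE",
    "BP_COMPONENT_CODES",
    "VITAL_SIGNS_CATEGORY_CODE",
    "BpComponentRule",
    "TransformContext",
    "classify_observation",
    "split_effective",
    "observation_to_measurement",
    "extract_bp_component",
    "observation_to_bp_rows",
    "patient_to_person",
    "encounter_to_visit",
    "practitioner_to_provider",
    "organization_to_care_site",
    "transform_bundle",
]

#: OHDSI standard concept: "measurement event id originates from measurement_id".
MEAS_EVENT_FIELD_CONCEPT_ID = 1147138

VITAL_SIGNS_CATEGORY_CODE = "vital-signs"


@dataclass(frozen=True)
class BpComponentRule:
    loinc_code: str
    label: str


SYSTOLIC_RULE = BpComponentRule("8480-6", "Systolic Blood Pressure")
DIASTOLIC_RULE = BpComponentRule("8462-4", "Diastolic Blood Pressure")
BP_COMPONENT_CODES = frozenset((SYSTOLIC_RULE.loinc_code, DIASTOLIC_RULE.loinc_code))


@dataclass
class TransformContext:
    """Concept maps by role, transformation constants and a warning sink."""

    maps: dict[str, ConceptMap]
    meas_event_field_concept_id: int = MEAS_EVENT_FIELD_CONCEPT_ID
    #: Optional type-concept overrides for context-specific runs, keyed
    #: "measurement" / "visit".  Empty by default: record-origin type
    #: concepts are not derivable from base FHIR resources.
    type_concepts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @classmethod
    def default(cls, maps_dir=None, **kwargs) -> "TransformContext":
        return cls(maps=load_shipped_maps(maps_dir), **kwargs)

    def translate_or_warn(
        self, role: str, code: Optional[str], system: Optional[str], where: str
    ) -> Optional[int]:
        """Translate, leaving the concept column empty (None) when unmapped."""
        if code is None:
            return None
        cmap = self.maps.get(role)
        if cmap is None:
            self.warnings.append(f"{where}: no {role!r} concept map configured")
            return None
        result = translate(code, system, cmap)
        if not result.mapped:
            result = translate(code, None, cmap)  # retry system-agnostically
        if not result.mapped:
            self.warnings.append(f"{where}: code {code!r} ({system}) unmapped in {role!r} map")
            return None
        return result.concept_id

    def code_inventory(self) -> frozenset[str]:
        cmap = self.maps.get("code")
        return frozenset(code for _, code in cmap.forward) if cmap else frozenset()


def classify_observation(obs: FhirObservation, ctx: TransformContext) -> str:
    """Route an Observation: ``"measurement"`` for quantitative vital signs,
    ``"unsupported"`` otherwise (qualitative observations belong to a
    different CDM table and are out of scope)."""
    for concept in obs.category:
        if concept.has_code(VITAL_SIGNS_CATEGORY_CODE):
            return "measurement"
    if obs.code is not None:
        inventory = ctx.code_inventory()
        if any(coding.code in inventory for coding in obs.code.coding):
            return "measurement"
    return "unsupported"


def split_effective(effective: str) -> tuple[str, Optional[str], str]:
    """Decompose a FHIR dateTime/instant into (date, time, datetime).

    The datetime part keeps the verbatim lexical form (timezone and all) so
    values survive a round trip unchanged; a date-only input yields an empty
    time and a midnight datetime.
    """
    if not effective:
        raise TransformError("empty effective[x] value")
    value = effective.strip()
    probe = value[:-1] + "+00:00" if value.endswith("Z") else value
    if "T" in value:
        try:
            datetime.fromisoformat(probe)
        except ValueError as exc:
            raise TransformError(f"unparseable dateTime {effective!r}") from exc
        date_part = value[:10]
        clock = value.split("T", 1)[1]
        for marker in ("+", "-", "Z"):
            idx = clock.find(marker)
            if idx != -1:
                clock = clock[:idx]
                break
        return date_part, clock, value
    try:
        datetime.strptime(value, "%Y-%m-%d")
    except ValueError as exc:
        raise TransformError(
            f"unparseable date {effective!r} (year-only and year-month forms are not "
            "precise enough for a Measurement date)"
        ) from exc
    return value, None, f"{value}T00:00:00"


def _reference_source(
    ref: Optional[ResourceReference], expected_table: str, ctx: TransformContext, where: str
) -> Optional[str]:
    if ref is None or ref.is_empty():
        return None
    table, source_value = resolve_logical_reference(ref)
    if table != expected_table:
        ctx.warnings.append(
            f"{where}: reference targets {table}, expected {expected_table}; ignored"
        )
        return None
    return source_value


def _first_practitioner(
    refs: list[ResourceReference], ctx: TransformContext, where: str
) -> Optional[str]:
    # OMOP has a single provider_id: the first Practitioner-typed reference wins.
    for ref in refs:
        if ref is None or ref.is_empty():
            continue
        try:
            table, source_value = resolve_logical_reference(ref)
        except Exception:
            continue
        if table == "provider":
            return source_value
        ctx.warnings.append(f"{where}: non-Practitioner performer ({table}) ignored")
    return None


def _primary_coding(concept: Optional[CodeableConcept]):
    return concept.first_code() if concept is not None else None


def _display_text(concept: Optional[CodeableConcept]) -> Optional[str]:
    if concept is None:
        return None
    if concept.text:
        return concept.text
    coding = concept.first_code()
    return coding.display if coding else None


def _quantity_fields(
    row: MeasurementRow, quantity: Quantity, ctx: TransformContext, where: str
) -> None:
    row.value_as_number = quantity.value
    if quantity.comparator:
        row.operator_concept_id = ctx.translate_or_warn(
            "operator", quantity.comparator, None, where
        )
    unit_token = quantity.code or quantity.unit
    row.unit_source_value = unit_token
    if unit_token:
        row.unit_concept_id = ctx.translate_or_warn(
            "unit", unit_token, quantity.system, where
        )


def _shared_measurement_fields(
    obs: FhirObservation, ctx: TransformContext, where: str
) -> MeasurementRow:
    if obs.subject is None or obs.subject.is_empty():
        raise TransformError(f"{where}: Observation.subject is required (person linkage)")
    row = MeasurementRow()
    row.person_id = _reference_source(obs.subject, "person", ctx, where)
    if row.person_id is None:
        raise TransformError(f"{where}: Observation.subject does not reference a Patient")
    row.visit_occurrence_id = _reference_source(obs.encounter, "visit_occurrence", ctx, where)
    row.provider_id = _first_practitioner(obs.performer, ctx, where)
    if obs.effective:
        row.measurement_date, row.measurement_time, row.measurement_datetime = split_effective(
            obs.effective
        )
    row.measurement_type_concept_id = ctx.type_concepts.get("measurement")
    return row


def observation_to_measurement(obs: FhirObservation, ctx: TransformContext) -> MeasurementRow:
    """Transform a single-value vital-sign Observation into one Measurement row.

    Populates the 18-column working set: identifiers, translated code,
    person/visit/provider linkage, the date/time/datetime triple, value and
    unit (operator when a comparator is present) and the reference range.
    Event-linkage columns stay empty — a single-value observation is one
    self-contained measurement.  Composite observations must go through
    :func:`observation_to_bp_rows` instead.
    """
    if obs.valueQuantity is None:
        raise TransformError(
            "Observation has no valueQuantity; composite (component-based) observations "
            "go through the blood-pressure split path"
        )
    bid = business_identifier(obs)
    where = f"Observation {bid}"
    row = _shared_measurement_fields(obs, ctx, where)
    row.measurement_id = bid
    row.measurement_source_value = bid
    coding = _primary_coding(obs.code)
    if coding is not None:
        row.measurement_concept_id = ctx.translate_or_warn(
            "code", coding.code, coding.system, where
        )
    _quantity_fields(row, obs.valueQuantity, ctx, where)
    row.value_source_value = _display_text(obs.code)
    if obs.referenceRange:
        rr = obs.referenceRange[0]
        row.range_low = rr.low.value if rr.low else None
        row.range_high = rr.high.value if rr.high else None
    return row


def extract_bp_component(
    obs: FhirObservation, rule: BpComponentRule, ctx: TransformContext
) -> MeasurementRow:
    """Apply one blood-pressure component rule (the conditional filter on the
    component's LOINC code) and emit that component's Measurement row."""
    component = obs.component_by_code(rule.loinc_code)
    if component is None or component.valueQuantity is None:
        raise TransformError(
            f"Observation has no valued component coded {rule.loinc_code} ({rule.label})"
        )
    bid = business_identifier(obs)
    where = f"Observation {bid} [{rule.label}]"
    row = _shared_measurement_fields(obs, ctx, where)
    # Unique per component, while measurement_source_value / measurement_event_id
    # keep the shared business identifier that links the pair.
    row.measurement_id = f"{bid}|{rule.loinc_code}"
    row.measurement_source_value = bid
    row.measurement_event_id = bid
    row.meas_event_field_concept_id = ctx.meas_event_field_concept_id
    row.measurement_concept_id = ctx.translate_or_warn("code", rule.loinc_code, None, where)
    _quantity_fields(row, component.valueQuantity, ctx, where)
    row.value_source_value = rule.label
    return row


def observation_to_bp_rows(
    obs: FhirObservation, ctx: TransformContext
) -> tuple[MeasurementRow, MeasurementRow]:
    """Split a composite blood-pressure Observation into (systolic, diastolic).

    The two rows share ``measurement_event_id`` and ``person_id`` and differ
    in ``measurement_concept_id``; a record is uniquely identified by the
    combination of measurement_id, measurement_concept_id and
    measurement_event_id.
    """
    missing = [
        rule.loinc_code
        for rule in (SYSTOLIC_RULE, DIASTOLIC_RULE)
        if obs.component_by_code(rule.loinc_code) is None
    ]
    if missing:
        raise TransformError(
            f"blood-pressure Observation is missing component(s) {', '.join(missing)}"
        )
    return (
        extract_bp_component(obs, SYSTOLIC_RULE, ctx),
        extract_bp_component(obs, DIASTOLIC_RULE, ctx),
    )


def _split_birth_date(birth_date: Optional[str]):
    if not birth_date:
        return None, None, None, None
    parts = birth_date.split("-")
    year = int(parts[0])
    month = int(parts[1]) if len(parts) > 1 else None
    day = int(parts[2]) if len(parts) > 2 else None
    birth_datetime = f"{birth_date}T00:00:00" if day is not None else None
    return year, month, day, birth_datetime


def patient_to_person(patient: FhirPatient, ctx: TransformContext) -> PersonRow:
    """Patient -> Person: gender through the gender map, date of birth
    decomposed into year/month/day plus birth_datetime, practitioner and
    organization linkage.  Race and ethnicity columns stay empty — base FHIR
    resources carry no such elements."""
    bid = business_identifier(patient)
    where = f"Patient {bid}"
    row = PersonRow(person_id=bid, person_source_value=bid)
    if patient.gender:
        concept = ctx.translate_or_warn("gender", patient.gender, None, where)
        row.gender_concept_id = concept
        row.gender_source_value = patient.gender
        row.gender_source_concept_id = concept
    (
        row.year_of_birth,
        row.month_of_birth,
        row.day_of_birth,
        row.birth_datetime,
    ) = _split_birth_date(patient.birthDate)
    if patient.generalPractitioner:
        row.provider_id = _reference_source(
            patient.generalPractitioner[0], "provider", ctx, where
        )
    row.care_site_id = _reference_source(
        patient.managingOrganization, "care_site", ctx, where
    )
    return row


def encounter_to_visit(encounter: FhirEncounter, ctx: TransformContext) -> VisitOccurrenceRow:
    """Encounter -> Visit Occurrence: class through the encounter-class map,
    actual period split into date/datetime pairs, admit source and discharge
    disposition through the place-of-service map.  visit_type_concept_id
    stays empty unless a context override supplies it."""
    bid = business_identifier(encounter)
    where = f"Encounter {bid}"
    row = VisitOccurrenceRow(visit_occurrence_id=bid, visit_source_value=bid)
    row.person_id = _reference_source(encounter.subject, "person", ctx, where)
    if encounter.class_ is not None and encounter.class_.code:
        row.visit_concept_id = ctx.translate_or_warn(
            "class", encounter.class_.code, encounter.class_.system, where
        )
    if encounter.actualPeriod is not None:
        if encounter.actualPeriod.start:
            row.visit_start_date, _, row.visit_start_datetime = split_effective(
                encounter.actualPeriod.start
            )
        if encounter.actualPeriod.end:
            row.visit_end_date, _, row.visit_end_datetime = split_effective(
                encounter.actualPeriod.end
            )
    row.provider_id = _first_practitioner(
        [p.actor for p in encounter.participant if p.actor is not None], ctx, where
    )
    row.care_site_id = _reference_source(encounter.serviceProvider, "care_site", ctx, where)
    if encounter.admission is not None:
        admit = _primary_coding(encounter.admission.admitSource)
        if admit is not None and admit.code:
            row.admitted_from_concept_id = ctx.translate_or_warn(
                "place-of-service", admit.code, admit.system, where
            )
            row.admitted_from_source_value = admit.code
        discharge = _primary_coding(encounter.admission.dischargeDisposition)
        if discharge is not None and discharge.code:
            row.discharged_to_concept_id = ctx.translate_or_warn(
                "place-of-service", discharge.code, discharge.system, where
            )
            row.discharged_to_source_value = discharge.code
    if encounter.partOf is not None and not encounter.partOf.is_empty():
        row.preceding_visit_occurrence_id = _reference_source(
            encounter.partOf, "visit_occurrence", ctx, where
        )
    row.visit_type_concept_id = ctx.type_concepts.get("visit")
    return row


def practitioner_to_provider(
    practitioner: FhirPractitioner, ctx: TransformContext
) -> ProviderRow:
    bid = business_identifier(practitioner)
    where = f"Practitioner {bid}"
    row = ProviderRow(provider_id=bid, provider_source_value=bid)
    if practitioner.name:
        row.provider_name = practitioner.name[0].display()
    if practitioner.birthDate:
        row.year_of_birth = int(practitioner.birthDate.split("-")[0])
    if practitioner.gender:
        concept = ctx.translate_or_warn("gender", practitioner.gender, None, where)
        row.gender_concept_id = concept
        row.gender_source_value = practitioner.gender
        row.gender_source_concept_id = concept
    return row


def organization_to_care_site(
    organization: FhirOrganization, ctx: TransformContext
) -> CareSiteRow:
    bid = business_identifier(organization)
    where = f"Organization {bid}"
    row = CareSiteRow(care_site_id=bid, care_site_source_value=bid)
    row.care_site_name = organization.name
    type_coding = _primary_coding(organization.type[0]) if organization.type else None
    if type_coding is not None and type_coding.code:
        row.place_of_service_concept_id = ctx.translate_or_warn(
            "place-of-service", type_coding.code, type_coding.system, where
        )
        row.place_of_service_source_value = type_coding.code
    return row


def transform_bundle(
    resources: Union[FhirBundle, list], ctx: TransformContext
) -> tuple[OmopRowSet, list[str]]:
    """Dispatch a mixed resource collection through the per-type rules.

    Blood-pressure observations (both components present) go through the
    split path.  Per-resource failures are collected in the returned report
    instead of aborting the batch.  Returns ``(logical rowset, errors)``.
    """
    if isinstance(resources, FhirBundle):
        resources = resources.entries
    rowset = OmopRowSet(provenance="logical")
    errors: list[str] = []
    for resource in resources:
        try:
            if isinstance(resource, FhirPatient):
                rowset.person.append(patient_to_person(resource, ctx))
            elif isinstance(resource, FhirEncounter):
                rowset.visit_occurrence.append(encounter_to_visit(resource, ctx))
            elif isinstance(resource, FhirPractitioner):
                rowset.provider.append(practitioner_to_provider(resource, ctx))
            elif isinstance(resource, FhirOrganization):
                rowset.care_site.append(organization_to_care_site(resource, ctx))
            elif isinstance(resource, FhirObservation):
                if classify_observation(resource, ctx) != "measurement":
                    errors.append(
                        f"Observation {resource.id or '?'}: not a quantitative vital "
                        "sign; unsupported"
                    )
                    continue
                if resource.component:
                    rowset.measurement.extend(observation_to_bp_rows(resource, ctx))
                else:
                    rowset.measurement.append(observation_to_measurement(resource, ctx))
            else:
                errors.append(
                    f"{getattr(resource, 'resourceType', type(resource).__name__)}: "
                    "unsupported resource type"
                )
        except Exception as exc:  # noqa: BLE001 — per-resource report, not an abort
            errors.append(str(exc))
    return rowset, errors
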
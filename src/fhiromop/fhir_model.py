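"""Typed in-memory model of the FHIR resources used for vital-signs exchange.

Covers the five source resource types (Observation, Patient, Encounter,
Practitioner, Organization) plus Bundle, targeting the R5 base element set;
R4 instances of the same core elements parse identically.  Only the elements
consumed by the transformation rules are modelled explicitly — everything
else (extensions, narrative, profile-specific elements) is retained opaquely
through pydantic's ``extra="allow"`` pass-through and survives a
serialize/parse round trip unchanged, but is never interpreted.

Element mandatoriness is deliberately *not* enforced at construction time:
resources are plain data holders, and FHIR-mandatory constraints are checked
at the I/O boundary (:func:`parse_resource`, :func:`serialize_resource`) and
by :func:`validate_observation`, so that invalid in-memory instances can be
built and inspected in tests and error paths.
"""

from __future__ import annotations

import json
from typing import Any, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

from fhiromop.errors import ParseError, UnsupportedResourceError, ValidityError

__all__ = [
    "Coding",
    "CodeableConcept",
    "Identifier",
    "Quantity",
    "ResourceReference",
    "ObservationComponent",
    "ObservationReferenceRange",
    "FhirObservation",
    "FhirPatient",
    "FhirEncounter",
    "FhirPractitioner",
    "FhirOrganization",
    "FhirBundle",
    "AnyResource",
    "parse_resource",
    "serialize_resource",
    "validate_observation",
]

COMPARATORS = ("<", "<=", ">=", ">")


class _Element(BaseModel):
    """Base for all FHIR element models: unknown children are kept verbatim."""

    model_config = ConfigDict(extra="allow", populate_by_name=True, validate_assignment=False)


class Coding(_Element):
    system: Optional[str] = None
    code: Optional[str] = None
    display: Optional[str] = None


class CodeableConcept(_Element):
    coding: list[Coding] = Field(default_factory=list)
    text: Optional[str] = None

    def first_code(self) -> Optional[Coding]:
        return self.coding[0] if self.coding else None

    def has_code(self, code: str, system: Optional[str] = None) -> bool:
        return any(
            c.code == code and (system is None or c.system is None or c.system == system)
            for c in self.coding
        )


class Identifier(_Element):
    system: Optional[str] = None
    value: Optional[str] = None


class Quantity(_Element):
    value: Optional[float] = None
    comparator: Optional[str] = None
    unit: Optional[str] = None
    system: Optional[str] = None
    code: Optional[str] = None  # UCUM token


class ResourceReference(_Element):
    """Literal (``Type/id``) or logical (identifier-based) resource reference."""

    reference: Optional[str] = None
    type: Optional[str] = None
    identifier: Optional[Identifier] = None
    display: Optional[str] = None

    def is_empty(self) -> bool:
        return self.reference is None and self.identifier is None


class ObservationComponent(_Element):
    code: CodeableConcept = Field(default_factory=CodeableConcept)
    valueQuantity: Optional[Quantity] = None


class ObservationReferenceRange(_Element):
    low: Optional[Quantity] = None
    high: Optional[Quantity] = None


class Period(_Element):
    start: Optional[str] = None
    end: Optional[str] = None


class _Resource(_Element):
    id: Optional[str] = None
    identifier: list[Identifier] = Field(default_factory=list)


class FhirObservation(_Resource):
    resourceType: str = "Observation"
    status: Optional[str] = None
    category: list[CodeableConcept] = Field(default_factory=list)
    code: Optional[CodeableConcept] = None
    subject: Optional[ResourceReference] = None
    encounter: Optional[ResourceReference] = None
    performer: list[ResourceReference] = Field(default_factory=list)
    effectiveDateTime: Optional[str] = None
    effectiveInstant: Optional[str] = None
    valueQuantity: Optional[Quantity] = None
    referenceRange: list[ObservationReferenceRange] = Field(default_factory=list)
    component: list[ObservationComponent] = Field(default_factory=list)

    @property
    def effective(self) -> Optional[str]:
        """The populated effective[x] choice (dateTime preferred over instant)."""
        return self.effectiveDateTime or self.effectiveInstant

    def component_by_code(self, code: str) -> Optional[ObservationComponent]:
        for comp in self.component:
            if comp.code.has_code(code):
                return comp
        return None


class FhirPatient(_Resource):
    resourceType: str = "Patient"
    gender: Optional[str] = None
    birthDate: Optional[str] = None
    generalPractitioner: list[ResourceReference] = Field(default_factory=list)
    managingOrganization: Optional[ResourceReference] = None


class EncounterParticipant(_Element):
    actor: Optional[ResourceReference] = None


class EncounterAdmission(_Element):
    admitSource: Optional[CodeableConcept] = None
    dischargeDisposition: Optional[CodeableConcept] = None


class FhirEncounter(_Resource):
    resourceType: str = "Encounter"
    class_: Optional[Coding] = Field(default=None, alias="class")
    subject: Optional[ResourceReference] = None
    actualPeriod: Optional[Period] = None
    participant: list[EncounterParticipant] = Field(default_factory=list)
    serviceProvider: Optional[ResourceReference] = None
    admission: Optional[EncounterAdmission] = None
    partOf: Optional[ResourceReference] = None


class HumanName(_Element):
    text: Optional[str] = None
    family: Optional[str] = None
    given: list[str] = Field(default_factory=list)

    def display(self) -> Optional[str]:
        if self.text:
            return self.text
        parts = [*self.given, self.family or ""]
        joined = " ".join(p for p in parts if p)
        return joined or None


class FhirPractitioner(_Resource):
    resourceType: str = "Practitioner"
    name: list[HumanName] = Field(default_factory=list)
    gender: Optional[str] = None
    birthDate: Optional[str] = None


class FhirOrganization(_Resource):
    resourceType: str = "Organization"
    name: Optional[str] = None
    type: list[CodeableConcept] = Field(default_factory=list)


AnyResource = Union[
    FhirObservation, FhirPatient, FhirEncounter, FhirPractitioner, FhirOrganization, "FhirBundle"
]


class BundleEntry(_Element):
    resource: Optional[dict[str, Any]] = None


class FhirBundle(_Element):
    resourceType: str = "Bundle"
    type: Optional[str] = None
    entry: list[BundleEntry] = Field(default_factory=list)

    @property
    def entries(self) -> list[AnyResource]:
        """Entry resources, parsed into their typed models."""
        return [_from_dict(e.resource) for e in self.entry if e.resource is not None]

    @classmethod
    def of(cls, resources: list[Any], type: str = "collection") -> "FhirBundle":
        return cls(
            type=type,
            entry=[BundleEntry(resource=_resource_dict(r)) for r in resources],
        )


_RESOURCE_TYPES: dict[str, type] = {
    "Observation": FhirObservation,
    "Patient": FhirPatient,
    "Encounter": FhirEncounter,
    "Practitioner": FhirPractitioner,
    "Organization": FhirOrganization,
    "Bundle": FhirBundle,
}


def _check_mandatory(resource: Any) -> None:
    if isinstance(resource, FhirObservation):
        if resource.status is None:
            raise ValidityError("Observation.status is mandatory but missing")
        if resource.code is None or not resource.code.coding:
            raise ValidityError("Observation.code is mandatory but missing or empty")


def _from_dict(payload: dict[str, Any]) -> AnyResource:
    rtype = payload.get("resourceType")
    if rtype is None:
        raise ParseError("JSON object has no resourceType field")
    model = _RESOURCE_TYPES.get(rtype)
    if model is None:
        raise UnsupportedResourceError(f"unsupported resourceType: {rtype!r}")
    resource = model.model_validate(payload)
    _check_mandatory(resource)
    return resource


def parse_resource(text: Union[str, bytes, dict]) -> AnyResource:
    """Parse FHIR JSON into a typed resource.

    Accepts a JSON string/bytes or an already-decoded dict.  Unknown elements
    are retained opaquely.  Raises :class:`ParseError` on malformed JSON or
    missing resourceType, :class:`UnsupportedResourceError` for resource
    types outside the supported six, and :class:`ValidityError` when a
    FHIR-mandatory element (Observation.status / Observation.code) is absent.
    """
    if isinstance(text, dict):
        payload = text
    else:
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"malformed JSON: {exc}") from exc
        if not isinstance(payload, dict):
            raise ParseError("top-level JSON value is not an object")
    return _from_dict(payload)


def _resource_dict(resource: Any) -> dict[str, Any]:
    return resource.model_dump(mode="json", by_alias=True, exclude_none=True, exclude_defaults=False)


def serialize_resource(resource: AnyResource, indent: Optional[int] = 2) -> str:
    """Serialize a typed resource to FHIR JSON (UTF-8 text).

    Round-trip contract: ``parse_resource(serialize_resource(r)) == r``.
    Raises :class:`ValidityError` when the resource violates a FHIR-mandatory
    constraint (so invalid instances cannot silently leave the process).
    """
    _check_mandatory(resource)
    return json.dumps(_resource_dict(resource), indent=indent, ensure_ascii=False)


def validate_observation(obs: FhirObservation) -> list[str]:
    """Check the minimal vital-sign Observation constraints; return violations.

    Empty result iff status is present, code carries at least one Coding, and
    exactly one of {valueQuantity, non-empty component list} is populated
    (single-value vital vs composite panel).  Violations are returned, never
    raised.
    """
    violations: list[str] = []
    if obs.status is None:
        violations.append("status: mandatory element is missing")
    if obs.code is None or not obs.code.coding:
        violations.append("code: at least one Coding is required")
    has_value = obs.valueQuantity is not None
    has_components = bool(obs.component)
    if has_value and has_components:
        violations.append(
            "value[x]/component: exactly one of valueQuantity or components expected, both present"
        )
    elif not has_value and not has_components:
        violations.append(
            "value[x]/component: exactly one of valueQuantity or components expected, neither present"
        )
    for i, comp in enumerate(obs.component):
        if not comp.code.coding:
            violations.append(f"component[{i}].code: at least one Coding is required")
    return violations
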
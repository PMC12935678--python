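"""OMOP -> FHIR reconstruction of vital-sign Observations.

Single-value Measurement rows map one-to-one onto Observation resources with
fixed defaults for elements the CDM does not store (status ``"final"`` —
only completed results ever reach the CDM — and a vital-signs category).
References are assembled from the de-identified integer keys with constant
type/system values: they are structurally valid but deliberately
non-functional, because the original identifiers are unrecoverable by
design.  For the same reason no Patient/Encounter/Practitioner/Organization
resource is ever reconstructed.

Blood-pressure pairs are merged in two stages mirroring the forward split:
rows are first linked on ``measurement_event_id`` (one systolic + one
diastolic concept), each row becomes an intermediate Observation, the two
are grouped in a collection Bundle, and the Bundle is folded into a single
composite Observation whose component values carry both readings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from fhiromop.concept_maps import reverse_translate, translate
from fhiromop.errors import AmbiguityError, TransformError
from fhiromop.fhir_model import (
    CodeableConcept,
    Coding,
    FhirBundle,
    FhirObservation,
    ObservationComponent,
    ObservationReferenceRange,
    Quantity,
    ResourceReference,
)
from fhiromop.forward_transform import DIASTOLIC_RULE, SYSTOLIC_RULE, TransformContext
from fhiromop.omop_model import MeasurementRow, OmopRowSet

__all__ = [
    "OBSERVATION_CATEGORY_SYSTEM",
    "VITAL_SIGNS_CATEGORY",
    "ReverseDefaults",
    "BpPair",
    "measurement_to_observation",
    "pair_bp_rows",
    "merge_bp_pair",
    "omop_to_fhir",
]

OBSERVATION_CATEGORY_SYSTEM = "http://terminology.hl7.org/CodeSystem/observation-category"

VITAL_SIGNS_CATEGORY = CodeableConcept(
    coding=[
        Coding(system=OBSERVATION_CATEGORY_SYSTEM, code="vital-signs", display="Vital Signs")
    ]
)

#: LOINC code of the blood-pressure panel used for the merged Observation.
BP_PANEL_CODE = "85354-9"


def _default_category() -> CodeableConcept:
    return VITAL_SIGNS_CATEGORY.model_copy(deep=True)


@dataclass
class ReverseDefaults:
    """Constants injected into reconstructed Observations."""

    status: str = "final"
    category: CodeableConcept = field(default_factory=_default_category)
    #: reference string prefix per key column; the resulting references are
    #: structurally valid but non-functional (de-identified keys only).
    reference_types: dict[str, str] = field(
        default_factory=lambda: {
            "person_id": "Patient",
            "visit_occurrence_id": "Encounter",
            "provider_id": "Practitioner",
        }
    )

    def __post_init__(self) -> None:
        if self.status != "final":
            raise TransformError('reverse status constant must be "final"')


_KEY_TABLE = {
    "person_id": "person",
    "visit_occurrence_id": "visit_occurrence",
    "provider_id": "provider",
}


def _surrogate_reference(
    defaults: ReverseDefaults, key_column: str, key_value
) -> ResourceReference:
    rtype = defaults.reference_types[key_column]
    table = _KEY_TABLE[key_column]
    return ResourceReference(reference=f"{rtype}/omop-{table}-{key_value}", type=rtype)


def measurement_to_observation(
    row: MeasurementRow,
    ctx: TransformContext,
    defaults: Optional[ReverseDefaults] = None,
) -> FhirObservation:
    """Reconstruct one single-value Observation from a Measurement row.

    The concept id is reverse-translated to a Coding; system and display
    come exclusively from the concept map's reverse entry (the original
    terminology system is not recoverable from the CDM).  Raises when the
    measurement concept has no reverse entry and the row carries no source
    code to fall back on.
    """
    defaults = defaults or ReverseDefaults()
    obs = FhirObservation(status=defaults.status, category=[defaults.category.model_copy(deep=True)])
    if row.measurement_id is not None:
        obs.id = str(row.measurement_id)

    code_result = reverse_translate(row.measurement_concept_id, ctx.maps["code"])
    if code_result.mapped:
        obs.code = CodeableConcept(
            coding=[code_result.coding], text=code_result.coding.display
        )
    elif row.measurement_source_value:
        obs.code = CodeableConcept(text=row.measurement_source_value)
    else:
        raise TransformError(
            f"measurement_concept_id {row.measurement_concept_id!r} has no reverse "
            "mapping and the row carries no source value"
        )

    unit_coding = None
    unit_result = reverse_translate(row.unit_concept_id, ctx.maps["unit"])
    if unit_result.mapped:
        unit_coding = unit_result.coding
    if row.value_as_number is not None:
        quantity = Quantity(value=row.value_as_number)
        if unit_coding is not None:
            quantity.code = unit_coding.code
            quantity.system = unit_coding.system
            quantity.unit = unit_coding.display or unit_coding.code
        elif row.unit_source_value:
            quantity.unit = row.unit_source_value
        operator_result = reverse_translate(row.operator_concept_id, ctx.maps["operator"])
        if operator_result.mapped:
            quantity.comparator = operator_result.coding.code
        obs.valueQuantity = quantity

    if row.range_low is not None or row.range_high is not None:
        rr = ObservationReferenceRange()
        if row.range_low is not None:
            rr.low = Quantity(value=row.range_low)
        if row.range_high is not None:
            rr.high = Quantity(value=row.range_high)
        if unit_coding is not None:
            for bound in (rr.low, rr.high):
                if bound is not None:
                    bound.code = unit_coding.code
                    bound.system = unit_coding.system
                    bound.unit = unit_coding.display or unit_coding.code
        obs.referenceRange = [rr]

    if row.measurement_datetime:
        obs.effectiveDateTime = row.measurement_datetime
    elif row.measurement_date:
        obs.effectiveDateTime = row.measurement_date

    if row.person_id is not None:
        obs.subject = _surrogate_reference(defaults, "person_id", row.person_id)
    if row.visit_occurrence_id is not None:
        obs.encounter = _surrogate_reference(
            defaults, "visit_occurrence_id", row.visit_occurrence_id
        )
    if row.provider_id is not None:
        obs.performer = [_surrogate_reference(defaults, "provider_id", row.provider_id)]
    return obs


@dataclass
class BpPair:
    """A linked systolic/diastolic Measurement pair sharing one event key."""

    systolic: MeasurementRow
    diastolic: MeasurementRow
    event_id: object = None

    def __post_init__(self) -> None:
        if self.event_id is None:
            self.event_id = self.systolic.measurement_event_id
        if self.systolic.measurement_event_id != self.diastolic.measurement_event_id:
            raise TransformError("blood-pressure pair rows disagree on measurement_event_id")
        if self.systolic.person_id != self.diastolic.person_id:
            raise TransformError("blood-pressure pair rows disagree on person_id")
        if self.systolic.measurement_datetime != self.diastolic.measurement_datetime:
            raise TransformError(
                "blood-pressure pair rows disagree on measurement_datetime"
            )
        if self.systolic.measurement_concept_id == self.diastolic.measurement_concept_id:
            raise TransformError("blood-pressure pair rows share one concept id")


def _bp_concept_ids(ctx: TransformContext) -> dict[int, str]:
    mapping = {}
    for rule in (SYSTOLIC_RULE, DIASTOLIC_RULE):
        result = translate(rule.loinc_code, None, ctx.maps["code"])
        if result.mapped:
            mapping[result.concept_id] = rule.loinc_code
    return mapping


def pair_bp_rows(
    rows: list[MeasurementRow], ctx: TransformContext
) -> tuple[list[BpPair], list[MeasurementRow]]:
    """Link blood-pressure rows on their shared event key.

    Greedy exact-key pairing: an event key with exactly one systolic and one
    diastolic row yields a pair; anything else (missing partner, no event
    key, foreign concept) is returned as a leftover, never silently dropped.
    Two same-side rows on one event key raise :class:`AmbiguityError`.
    """
    concept_codes = _bp_concept_ids(ctx)
    sys_concept = next(
        (cid for cid, code in concept_codes.items() if code == SYSTOLIC_RULE.loinc_code), None
    )
    pairs: list[BpPair] = []
    leftovers: list[MeasurementRow] = []
    groups: dict[object, list[MeasurementRow]] = {}
    for row in rows:
        if (
            row.measurement_event_id is not None
            and row.measurement_concept_id in concept_codes
        ):
            groups.setdefault(row.measurement_event_id, []).append(row)
        else:
            leftovers.append(row)
    for event_id, group in groups.items():
        systolic = [r for r in group if r.measurement_concept_id == sys_concept]
        diastolic = [r for r in group if r.measurement_concept_id != sys_concept]
        if len(systolic) > 1 or len(diastolic) > 1:
            side = "systolic" if len(systolic) > 1 else "diastolic"
            raise AmbiguityError(
                f"event id {event_id!r}: {side} measurement is ambiguous "
                f"({max(len(systolic), len(diastolic))} rows)"
            )
        if len(systolic) == 1 and len(diastolic) == 1:
            pairs.append(BpPair(systolic=systolic[0], diastolic=diastolic[0]))
        else:
            leftovers.extend(group)
    return pairs, leftovers


def merge_bp_pair(
    pair: BpPair, ctx: TransformContext, defaults: Optional[ReverseDefaults] = None
) -> FhirObservation:
    """Fold a linked pair into one composite blood-pressure Observation.

    Stage one builds the two intermediate Observations and groups them in a
    collection Bundle; stage two merges the Bundle into a single resource:
    both values land in ``Observation.component.value``, shared elements
    (subject, encounter, performer, effective, status, category) are taken
    from the systolic intermediate, there is no top-level valueQuantity, and
    no human-readable text is synthesized (it cannot be attributed to either
    component unambiguously).
    """
    defaults = defaults or ReverseDefaults()
    intermediates = [
        measurement_to_observation(row, ctx, defaults)
        for row in (pair.systolic, pair.diastolic)
    ]
    bundle = FhirBundle.of(intermediates, type="collection")

    sys_obs, dia_obs = bundle.entries
    merged = FhirObservation(
        status=sys_obs.status,
        category=[c.model_copy(deep=True) for c in sys_obs.category],
        subject=sys_obs.subject,
        encounter=sys_obs.encounter,
        performer=list(sys_obs.performer),
        effectiveDateTime=sys_obs.effectiveDateTime,
    )
    if pair.event_id is not None:
        merged.id = f"bp-{pair.event_id}"
    panel = translate(BP_PANEL_CODE, None, ctx.maps["code"])
    panel_coding = None
    if panel.mapped:
        reverse = reverse_translate(panel.concept_id, ctx.maps["code"])
        panel_coding = reverse.coding if reverse.mapped else None
    merged.code = CodeableConcept(
        coding=[panel_coding] if panel_coding is not None else []
    )
    for intermediate in (sys_obs, dia_obs):
        if intermediate.code is None or intermediate.valueQuantity is None:
            raise TransformError("intermediate blood-pressure Observation is incomplete")
        merged.component.append(
            ObservationComponent(
                code=intermediate.code.model_copy(deep=True),
                valueQuantity=intermediate.valueQuantity.model_copy(deep=True),
            )
        )
    return merged


def omop_to_fhir(
    rowset: OmopRowSet, ctx: TransformContext, defaults: Optional[ReverseDefaults] = None
) -> tuple[list[FhirObservation], list[str]]:
    """Reconstruct Observations for a whole Measurement rowset.

    Blood-pressure pairs are merged; every other measurement converts singly.
    Rows that cannot convert are reported, never dropped silently.  No
    person-level resource is ever emitted: the identifying elements a usable
    Patient resource would need do not exist in the CDM.
    """
    defaults = defaults or ReverseDefaults()
    report: list[str] = []
    observations: list[FhirObservation] = []
    pairs, singles = pair_bp_rows(rowset.measurement, ctx)
    for pair in pairs:
        try:
            observations.append(merge_bp_pair(pair, ctx, defaults))
        except Exception as exc:  # noqa: BLE001
            report.append(f"event {pair.event_id!r}: {exc}")
    for row in singles:
        if row.measurement_event_id is not None:
            report.append(
                f"measurement {row.measurement_id!r}: unpaired blood-pressure row "
                f"(event {row.measurement_event_id!r})"
            )
            continue
        try:
            observations.append(measurement_to_observation(row, ctx, defaults))
        except Exception as exc:  # noqa: BLE001
            report.append(f"measurement {row.measurement_id!r}: {exc}")
    return observations, report
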
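"""Deterministic generator of internally consistent FHIR vital-signs cohorts.

Produces one Organization, a small practitioner pool, ``n_patients``
Patients with one Encounter each (plus one follow-up Encounter so visit
chaining is exercised) and a stream of vital-sign Observations: eight
single-value types and composite blood pressure, all cross-referenced with
logical (identifier-based) references that resolve within the cohort.

Value distributions are conventional physiologic ranges (temperature
~N(37.0, 0.5) degC, systolic ~N(120, 15) and diastolic ~N(80, 10) mmHg, and
documented equivalents for the rest) — plausible stand-ins for example
instances, not fitted to any dataset.  The vital-sign mix is allocated by
largest-remainder apportionment of the configured weights and then
shuffled, so with the default uniform weights every type (including blood
pressure) appears whenever the cohort has at least nine observations.  The
seed fully determines the output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from fhiromop.errors import ConfigError, FhirOmopError
from fhiromop.fhir_model import (
    CodeableConcept,
    Coding,
    EncounterAdmission,
    EncounterParticipant,
    FhirEncounter,
    FhirObservation,
    FhirOrganization,
    FhirPatient,
    FhirPractitioner,
    HumanName,
    Identifier,
    ObservationComponent,
    ObservationReferenceRange,
    Period,
    Quantity,
    ResourceReference,
)
from fhiromop.reverse_transform import OBSERVATION_CATEGORY_SYSTEM

__all__ = [
    "VITAL_TYPES",
    "BLOOD_PRESSURE",
    "CohortConfig",
    "generate_cohort",
    "generate_single_vital",
    "generate_bp_observation",
]

LOINC = "http://loinc.org"
UCUM = "http://unitsofmeasure.org"

_SYSTEMS = {
    "patient": "https://example.org/fhir/mrn",
    "encounter": "https://example.org/fhir/encounters",
    "practitioner": "https://example.org/fhir/practitioners",
    "organization": "https://example.org/fhir/organizations",
    "observation": "https://example.org/fhir/observations",
}


@dataclass(frozen=True)
class VitalSpec:
    key: str
    code: str
    display: str
    unit: str  # UCUM token
    mean: float
    sd: float
    range_low: float
    range_high: float
    decimals: int = 1


#: The eight single-value vital-sign types (key -> spec).
VITAL_TYPES: dict[str, VitalSpec] = {
    spec.key: spec
    for spec in (
        VitalSpec("temperature", "8310-5", "Body temperature", "Cel", 37.0, 0.5, 36.1, 38.0),
        VitalSpec("respiratory-rate", "9279-1", "Respiratory rate", "/min", 16.0, 3.0, 12.0, 20.0, 0),
        VitalSpec("heart-rate", "8867-4", "Heart rate", "/min", 75.0, 12.0, 60.0, 100.0, 0),
        VitalSpec(
            "oxygen-saturation",
            "2708-6",
            "Oxygen saturation in Arterial blood",
            "%",
            97.0,
            1.5,
            94.0,
            100.0,
            0,
        ),
        VitalSpec("body-weight", "29463-7", "Body weight", "kg", 75.0, 12.0, 50.0, 100.0),
        VitalSpec("body-height", "8302-2", "Body height", "cm", 170.0, 10.0, 150.0, 190.0),
        VitalSpec(
            "head-circumference",
            "9843-4",
            "Head Occipital-frontal circumference",
            "cm",
            56.0,
            2.0,
            52.0,
            60.0,
        ),
        VitalSpec("bmi", "39156-5", "Body mass index (BMI) [Ratio]", "kg/m2", 24.0, 3.5, 18.5, 24.9),
    )
}

BLOOD_PRESSURE = "blood-pressure"
BP_PANEL = VitalSpec(
    BLOOD_PRESSURE, "85354-9", "Blood pressure panel with all children optional", "mm[Hg]", 0, 0, 0, 0
)
BP_SYSTOLIC = VitalSpec(
    "bp-systolic", "8480-6", "Systolic blood pressure", "mm[Hg]", 120.0, 15.0, 90.0, 140.0, 0
)
BP_DIASTOLIC = VitalSpec(
    "bp-diastolic", "8462-4", "Diastolic blood pressure", "mm[Hg]", 80.0, 10.0, 60.0, 90.0, 0
)

_ALL_KEYS = (*VITAL_TYPES, BLOOD_PRESSURE)


def _default_mix() -> dict[str, float]:
    return {key: 1.0 for key in _ALL_KEYS}


def _default_missingness() -> dict[str, float]:
    # element -> probability of omission; 0 keeps the happy path fully populated
    return {"encounter": 0.0, "performer": 0.0, "referenceRange": 0.0}


@dataclass
class CohortConfig:
    seed: int = 0
    n_patients: int = 5
    observations_per_patient: int = 4
    n_practitioners: int = 2
    vital_mix: dict[str, float] = field(default_factory=_default_mix)
    missingness: dict[str, float] = field(default_factory=_default_missingness)
    #: probability that an oxygen-saturation reading carries a ">=" comparator
    comparator_rate: float = 0.1

    def validate(self) -> None:
        if self.n_patients < 1 or self.observations_per_patient < 0 or self.n_practitioners < 1:
            raise ConfigError("cohort sizes must be positive")
        unknown = set(self.vital_mix) - set(_ALL_KEYS)
        if unknown:
            raise ConfigError(f"unknown vital-sign type(s) in mix: {sorted(unknown)}")
        if any(w < 0 for w in self.vital_mix.values()):
            raise ConfigError("vital-sign mix weights must be nonnegative")
        if sum(self.vital_mix.values()) <= 0:
            raise ConfigError("vital-sign mix weights sum to zero")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missingness rate for {name!r} outside [0, 1]")


def _logical_ref(resource_type: str, system: str, value: str) -> ResourceReference:
    return ResourceReference(type=resource_type, identifier=Identifier(system=system, value=value))


def _vital_category() -> CodeableConcept:
    return CodeableConcept(
        coding=[
            Coding(
                system=OBSERVATION_CATEGORY_SYSTEM, code="vital-signs", display="Vital Signs"
            )
        ]
    )


def _quantity(value: float, unit: str, comparator: Optional[str] = None) -> Quantity:
    return Quantity(value=value, unit=unit, system=UCUM, code=unit, comparator=comparator)


def _draw_value(rng: random.Random, spec: VitalSpec) -> float:
    value = rng.gauss(spec.mean, spec.sd)
    if spec.key == "oxygen-saturation":
        value = min(value, 100.0)
    value = round(value, spec.decimals)
    return float(value) if spec.decimals else float(int(value))


def generate_single_vital(
    seed: int,
    code: str,
    subject: ResourceReference,
    encounter: Optional[ResourceReference] = None,
    performer: Optional[ResourceReference] = None,
    effective: str = "2024-03-01T10:30:00Z",
    identifier_value: Optional[str] = None,
    comparator: Optional[str] = None,
) -> FhirObservation:
    """One single-value vital-sign Observation (valueQuantity + referenceRange)."""
    spec = next((s for s in VITAL_TYPES.values() if s.code == code), None)
    if spec is None:
        raise FhirOmopError(f"unknown single-value vital-sign LOINC code {code!r}")
    rng = random.Random(seed)
    value = _draw_value(rng, spec)
    obs = FhirObservation(
        identifier=[
            Identifier(
                system=_SYSTEMS["observation"],
                value=identifier_value or f"OBS-{spec.key}-{seed}",
            )
        ],
        status="final",
        category=[_vital_category()],
        code=CodeableConcept(
            coding=[Coding(system=LOINC, code=spec.code, display=spec.display)],
            text=spec.display,
        ),
        subject=subject,
        encounter=encounter,
        performer=[performer] if performer is not None else [],
        effectiveDateTime=effective,
        valueQuantity=_quantity(value, spec.unit, comparator),
        referenceRange=[
            ObservationReferenceRange(
                low=_quantity(spec.range_low, spec.unit),
                high=_quantity(spec.range_high, spec.unit),
            )
        ],
    )
    return obs


def generate_bp_observation(
    seed: int,
    subject: ResourceReference,
    encounter: Optional[ResourceReference] = None,
    performer: Optional[ResourceReference] = None,
    effective: str = "2024-03-01T10:30:00Z",
    identifier_value: Optional[str] = None,
) -> FhirObservation:
    """One composite blood-pressure Observation: systolic and diastolic
    components (LOINC 8480-6 / 8462-4), no top-level value."""
    rng = random.Random(seed)
    systolic = _draw_value(rng, BP_SYSTOLIC)
    diastolic = min(_draw_value(rng, BP_DIASTOLIC), systolic - 10.0)

    def component(spec: VitalSpec, value: float) -> ObservationComponent:
        return ObservationComponent(
            code=CodeableConcept(
                coding=[Coding(system=LOINC, code=spec.code, display=spec.display)],
                text=spec.display,
            ),
            valueQuantity=_quantity(value, spec.unit),
        )

    return FhirObservation(
        identifier=[
            Identifier(
                system=_SYSTEMS["observation"], value=identifier_value or f"OBS-bp-{seed}"
            )
        ],
        status="final",
        category=[_vital_category()],
        code=CodeableConcept(
            coding=[Coding(system=LOINC, code=BP_PANEL.code, display=BP_PANEL.display)],
            text=BP_PANEL.display,
        ),
        subject=subject,
        encounter=encounter,
        performer=[performer] if performer is not None else [],
        effectiveDateTime=effective,
        component=[component(BP_SYSTOLIC, systolic), component(BP_DIASTOLIC, diastolic)],
    )


def _apportion(weights: dict[str, float], total: int) -> list[str]:
    """Largest-remainder allocation of `total` slots over the weighted types."""
    weight_sum = sum(weights.values())
    shares = {key: total * w / weight_sum for key, w in weights.items() if w > 0}
    counts = {key: int(share) for key, share in shares.items()}
    remainder = total - sum(counts.values())
    by_fraction = sorted(shares, key=lambda k: shares[k] - counts[k], reverse=True)
    for key in by_fraction[:remainder]:
        counts[key] += 1
    sequence: list[str] = []
    for key, count in counts.items():
        sequence.extend([key] * count)
    return sequence


def generate_cohort(config: CohortConfig) -> list:
    """Generate a fully cross-referenced vital-signs cohort.

    Output order: Organization, Practitioners, then per patient the Patient,
    Encounter(s) and Observations.  Every reference resolves within the
    cohort and every emitted code/unit/comparator is covered by the shipped
    concept maps.  The same config (seed included) reproduces the identical
    resource list.
    """
    config.validate()
    rng = random.Random(config.seed)

    org_id = "ORG-001"
    organization = FhirOrganization(
        identifier=[Identifier(system=_SYSTEMS["organization"], value=org_id)],
        name="Synthetic Vitals Clinic",
        type=[
            CodeableConcept(
                coding=[
                    Coding(
                        system="http://terminology.hl7.org/CodeSystem/organization-type",
                        code="prov",
                        display="Healthcare Provider",
                    )
                ]
            )
        ],
    )
    org_ref = _logical_ref("Organization", _SYSTEMS["organization"], org_id)

    practitioners = []
    practitioner_refs = []
    for i in range(config.n_practitioners):
        pid = f"PRACT-{i + 1:03d}"
        practitioners.append(
            FhirPractitioner(
                identifier=[Identifier(system=_SYSTEMS["practitioner"], value=pid)],
                name=[HumanName(family=f"Practitioner{i + 1}", given=["Synth"])],
                gender=rng.choice(["male", "female"]),
                birthDate=f"{rng.randint(1955, 1990)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
            )
        )
        practitioner_refs.append(
            _logical_ref("Practitioner", _SYSTEMS["practitioner"], pid)
        )

    resources: list = [organization, *practitioners]
    total_obs = config.n_patients * config.observations_per_patient
    type_sequence = _apportion(config.vital_mix, total_obs)
    rng.shuffle(type_sequence)
    obs_counter = 0

    def _omit(element: str) -> bool:
        rate = config.missingness.get(element, 0.0)
        return rate > 0 and rng.random() < rate

    for p in range(config.n_patients):
        mrn = f"PAT-{p + 1:03d}"
        patient_ref = _logical_ref("Patient", _SYSTEMS["patient"], mrn)
        practitioner_ref = practitioner_refs[p % len(practitioner_refs)]
        patient = FhirPatient(
            identifier=[Identifier(system=_SYSTEMS["patient"], value=mrn)],
            gender=rng.choice(["male", "female"]),
            birthDate=f"{rng.randint(1940, 2009)}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
            generalPractitioner=[practitioner_ref],
            managingOrganization=org_ref,
        )
        resources.append(patient)

        enc_id = f"ENC-{p + 1:03d}"
        encounter_ref = _logical_ref("Encounter", _SYSTEMS["encounter"], enc_id)
        day = f"2024-03-{rng.randint(1, 28):02d}"
        start_h = rng.randint(7, 15)
        start = f"{day}T{start_h:02d}:{rng.randint(0, 59):02d}:00Z"
        end = f"{day}T{start_h + 2:02d}:{rng.randint(0, 59):02d}:00Z"
        encounter = FhirEncounter(
            identifier=[Identifier(system=_SYSTEMS["encounter"], value=enc_id)],
            **{"class": Coding(
                system="http://terminology.hl7.org/CodeSystem/v3-ActCode",
                code=rng.choice(["AMB", "AMB", "AMB", "IMP"]),
                display="ambulatory",
            )},
            subject=patient_ref,
            actualPeriod=Period(start=start, end=end),
            participant=[EncounterParticipant(actor=practitioner_ref)],
            serviceProvider=org_ref,
            admission=EncounterAdmission(
                admitSource=CodeableConcept(
                    coding=[
                        Coding(
                            system="http://terminology.hl7.org/CodeSystem/admit-source",
                            code=rng.choice(["gp", "emd"]),
                        )
                    ]
                ),
                dischargeDisposition=CodeableConcept(
                    coding=[
                        Coding(
                            system="http://terminology.hl7.org/CodeSystem/discharge-disposition",
                            code=rng.choice(["home", "home", "snf"]),
                        )
                    ]
                ),
            ),
        )
        resources.append(encounter)

        if p == 0:
            # follow-up visit chained to the first one: exercises visit linkage
            fu_id = f"ENC-{p + 1:03d}-FU"
            followup = encounter.model_copy(deep=True)
            followup.identifier = [Identifier(system=_SYSTEMS["encounter"], value=fu_id)]
            fu_day = f"2024-04-{rng.randint(1, 28):02d}"
            followup.actualPeriod = Period(
                start=f"{fu_day}T09:00:00Z", end=f"{fu_day}T10:00:00Z"
            )
            followup.partOf = encounter_ref
            resources.append(followup)

        for _ in range(config.observations_per_patient):
            vital_key = type_sequence[obs_counter]
            obs_counter += 1
            obs_seed = (config.seed * 100003 + obs_counter * 101) % (2**31)
            minute = rng.randint(0, 59)
            effective = f"{day}T{start_h:02d}:{minute:02d}:00Z"
            subject = patient_ref
            enc_ref = None if _omit("encounter") else encounter_ref
            perf_ref = None if _omit("performer") else practitioner_ref
            obs_identifier = f"OBS-{obs_counter:05d}"
            if vital_key == BLOOD_PRESSURE:
                obs = generate_bp_observation(
                    obs_seed,
                    subject,
                    encounter=enc_ref,
                    performer=perf_ref,
                    effective=effective,
                    identifier_value=obs_identifier,
                )
            else:
                spec = VITAL_TYPES[vital_key]
                comparator = None
                if spec.key == "oxygen-saturation" and rng.random() < config.comparator_rate:
                    comparator = ">="
                obs = generate_single_vital(
                    obs_seed,
                    spec.code,
                    subject,
                    encounter=enc_ref,
                    performer=perf_ref,
                    effective=effective,
                    identifier_value=obs_identifier,
                    comparator=comparator,
                )
                if _omit("referenceRange"):
                    obs.referenceRange = []
            resources.append(obs)
    return resources
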
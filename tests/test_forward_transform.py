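"""Forward FHIR -> OMOP transformation rules, including the blood-pressure split."""

import pytest

from fhiromop.errors import TransformError
from fhiromop.fhir_model import (
    CodeableConcept,
    Coding,
    FhirObservation,
    FhirPatient,
    Identifier,
    Quantity,
    ResourceReference,
    parse_resource,
)
from fhiromop.forward_transform import (
    DIASTOLIC_RULE,
    MEAS_EVENT_FIELD_CONCEPT_ID,
    SYSTOLIC_RULE,
    classify_observation,
    encounter_to_visit,
    extract_bp_component,
    observation_to_bp_rows,
    observation_to_measurement,
    patient_to_person,
    split_effective,
    transform_bundle,
)
from fhiromop.synthetic_data import (
    CohortConfig,
    generate_bp_observation,
    generate_cohort,
    generate_single_vital,
)

PATIENT_REF = ResourceReference(
    type="Patient", identifier=Identifier(system="s", value="p1")
)


def make_temperature(value=37.9, comparator=None, with_range=True):
    obs = generate_single_vital(
        7, "8310-5", PATIENT_REF, identifier_value="OBS-T1", comparator=comparator
    )
    obs.valueQuantity.value = value
    if not with_range:
        obs.referenceRange = []
    return obs


class TestSplitEffective:
    @pytest.mark.parametrize(
        "value, expected",
        [
            ("2024-03-01T10:30:00", ("2024-03-01", "10:30:00", "2024-03-01T10:30:00")),
            ("2024-03-01T10:30:00Z", ("2024-03-01", "10:30:00", "2024-03-01T10:30:00Z")),
            (
                "2024-03-01T10:30:00+02:00",
                ("2024-03-01", "10:30:00", "2024-03-01T10:30:00+02:00"),
            ),
            ("2024-03-01", ("2024-03-01", None, "2024-03-01T00:00:00")),
        ],
    )
    def test_decomposition(self, value, expected):
        assert split_effective(value) == expected

    @pytest.mark.parametrize("bad", ["not-a-date", "", "2024", "2024-13-01"])
    def test_unparseable_raises(self, bad):
        with pytest.raises(TransformError):
            split_effective(bad)


class TestClassify:
    def test_vital_signs_category_routes_to_measurement(self, ctx):
        assert classify_observation(make_temperature(), ctx) == "measurement"

    def test_bp_panel_routes_to_measurement(self, ctx):
        obs = generate_bp_observation(3, PATIENT_REF)
        assert classify_observation(obs, ctx) == "measurement"

    def test_survey_category_is_unsupported(self, ctx):
        obs = FhirObservation(
            status="final",
            category=[CodeableConcept(coding=[Coding(code="survey")])],
            code=CodeableConcept(coding=[Coding(code="72166-2")]),
        )
        assert classify_observation(obs, ctx) == "unsupported"


class TestSingleValueMeasurement:
    def test_temperature_expected_row(self, ctx):
        obs = make_temperature(37.9)
        obs.effectiveDateTime = "2024-03-01T10:30:00Z"
        row = observation_to_measurement(obs, ctx)
        assert row.value_as_number == 37.9
        assert row.unit_source_value == "Cel"
        assert row.operator_concept_id is None
        assert row.measurement_id == row.measurement_source_value
        assert "OBS-T1" in str(row.measurement_id)
        assert row.person_id == "s|p1"
        assert (row.measurement_date, row.measurement_time, row.measurement_datetime) == (
            "2024-03-01",
            "10:30:00",
            "2024-03-01T10:30:00Z",
        )
        assert row.measurement_concept_id is not None  # mapped through the code map
        assert row.value_source_value == "Body temperature"
        # event linkage intentionally empty for single-value observations
        assert row.measurement_event_id is None and row.meas_event_field_concept_id is None
        # untransformed working-model columns stay empty
        assert row.measurement_type_concept_id is None
        assert row.value_as_concept_id is None
        assert row.measurement_source_concept_id is None
        assert row.unit_source_concept_id is None

    def test_reference_range_copied_exactly(self, ctx):
        row = observation_to_measurement(make_temperature(), ctx)
        assert (row.range_low, row.range_high) == (36.1, 38.0)

    def test_comparator_maps_to_operator_concept(self, fresh_ctx):
        obs = generate_single_vital(
            5, "2708-6", PATIENT_REF, comparator=">=", identifier_value="OBS-S1"
        )
        row = observation_to_measurement(obs, fresh_ctx)
        assert row.operator_concept_id is not None
        assert fresh_ctx.warnings == []

    def test_component_observation_refused(self, ctx):
        with pytest.raises(TransformError, match="blood-pressure"):
            observation_to_measurement(generate_bp_observation(3, PATIENT_REF), ctx)

    def test_missing_subject_refused(self, ctx):
        obs = make_temperature()
        obs.subject = None
        with pytest.raises(TransformError, match="subject"):
            observation_to_measurement(obs, ctx)

    def test_unmapped_code_leaves_concept_empty_with_warning(self, fresh_ctx):
        obs = make_temperature()
        obs.code = CodeableConcept(coding=[Coding(system="http://loinc.org", code="0000-0")])
        row = observation_to_measurement(obs, fresh_ctx)
        assert row.measurement_concept_id is None
        assert any("unmapped" in w for w in fresh_ctx.warnings)


class TestBloodPressureSplit:
    @pytest.fixture()
    def bp_obs(self):
        return generate_bp_observation(11, PATIENT_REF, identifier_value="OBS-BP1")

    def test_two_rows_with_shared_event_key(self, bp_obs, ctx):
        systolic, diastolic = observation_to_bp_rows(bp_obs, ctx)
        assert systolic.measurement_event_id == diastolic.measurement_event_id
        assert systolic.person_id == diastolic.person_id
        assert systolic.measurement_concept_id != diastolic.measurement_concept_id
        assert systolic.measurement_id != diastolic.measurement_id

    def test_event_field_concept_is_1147138_on_both(self, bp_obs, ctx):
        for row in observation_to_bp_rows(bp_obs, ctx):
            assert row.meas_event_field_concept_id == MEAS_EVENT_FIELD_CONCEPT_ID == 1147138

    def test_values_and_labels_follow_the_component_rules(self, bp_obs, ctx):
        systolic, diastolic = observation_to_bp_rows(bp_obs, ctx)
        assert systolic.value_as_number == bp_obs.component_by_code("8480-6").valueQuantity.value
        assert diastolic.value_as_number == bp_obs.component_by_code("8462-4").valueQuantity.value
        assert systolic.value_source_value == "Systolic Blood Pressure"
        assert diastolic.value_source_value == "Diastolic Blood Pressure"

    def test_diastolic_rule_on_systolic_only_observation(self, bp_obs, ctx):
        bp_obs.component = bp_obs.component[:1]  # keep systolic only
        with pytest.raises(TransformError, match="8462-4"):
            extract_bp_component(bp_obs, DIASTOLIC_RULE, ctx)
        with pytest.raises(TransformError):
            observation_to_bp_rows(bp_obs, ctx)

    def test_rules_are_exactly_systolic_and_diastolic(self):
        assert SYSTOLIC_RULE.loinc_code == "8480-6"
        assert DIASTOLIC_RULE.loinc_code == "8462-4"


class TestContextTables:
    def test_patient_decomposition(self, ctx):
        patient = FhirPatient(
            identifier=[Identifier(system="s", value="p1")],
            gender="female",
            birthDate="1980-05-02",
        )
        row = patient_to_person(patient, ctx)
        assert (row.year_of_birth, row.month_of_birth, row.day_of_birth) == (1980, 5, 2)
        assert row.birth_datetime == "1980-05-02T00:00:00"
        assert row.gender_source_value == "female"
        assert row.gender_concept_id is not None
        assert row.race_concept_id is None and row.ethnicity_concept_id is None

    def test_organization_to_care_site(self, ctx, cohort):
        org = cohort[0]
        from fhiromop.forward_transform import organization_to_care_site

        row = organization_to_care_site(org, ctx)
        assert row.care_site_name == "Synthetic Vitals Clinic"
        assert row.location_id is None
        assert row.place_of_service_concept_id is not None

    def test_encounter_without_end_leaves_end_empty(self, ctx, cohort):
        from fhiromop.fhir_model import FhirEncounter

        encounter = next(r for r in cohort if isinstance(r, FhirEncounter)).model_copy(deep=True)
        encounter.actualPeriod.end = None
        row = encounter_to_visit(encounter, ctx)
        assert row.visit_end_date is None and row.visit_end_datetime is None
        assert row.visit_start_date is not None
        assert row.visit_type_concept_id is None


class TestTransformBundle:
    def test_counting_one_of_each(self, ctx, cohort):
        patient = next(r for r in cohort if r.resourceType == "Patient")
        encounter = next(r for r in cohort if r.resourceType == "Encounter")
        temp = make_temperature()
        rowset, errors = transform_bundle([patient, encounter, temp], ctx)
        assert errors == []
        assert rowset.counts() == {
            "care_site": 0,
            "provider": 0,
            "person": 1,
            "visit_occurrence": 1,
            "measurement": 1,
        }

    def test_bp_observation_yields_two_measurements(self, ctx):
        patient = FhirPatient(identifier=[Identifier(system="s", value="p1")])
        rowset, errors = transform_bundle(
            [patient, generate_bp_observation(2, PATIENT_REF)], ctx
        )
        assert errors == []
        assert rowset.counts()["measurement"] == 2

    def test_empty_input(self, ctx):
        rowset, errors = transform_bundle([], ctx)
        assert errors == [] and sum(rowset.counts().values()) == 0

    def test_per_resource_errors_do_not_abort(self, ctx):
        broken = make_temperature()
        broken.subject = None
        rowset, errors = transform_bundle([broken, make_temperature()], ctx)
        assert len(errors) == 1 and rowset.counts()["measurement"] == 1

    def test_numeric_fidelity_no_rounding(self, ctx):
        obs = make_temperature(36.8500001)
        row = observation_to_measurement(obs, ctx)
        assert row.value_as_number == 36.8500001


def test_default_cohort_transforms_without_warnings():
    """Happy-path totality: every generated code/unit/comparator translates."""
    from fhiromop.forward_transform import TransformContext

    ctx = TransformContext.default()
    rowset, errors = transform_bundle(generate_cohort(CohortConfig(seed=3)), ctx)
    assert errors == [] and ctx.warnings == []
    assert rowset.counts()["measurement"] >= 20
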
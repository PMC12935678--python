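"""OMOP -> FHIR reconstruction and the Bundle-based blood-pressure merge."""

import json

import pytest

from fhiromop.errors import AmbiguityError
from fhiromop.fhir_model import (
    Identifier,
    ResourceReference,
    serialize_resource,
)
from fhiromop.forward_transform import (
    observation_to_bp_rows,
    observation_to_measurement,
    transform_bundle,
)
from fhiromop.key_management import finalize_physical
from fhiromop.omop_model import MeasurementRow, OmopRowSet
from fhiromop.reverse_transform import (
    measurement_to_observation,
    merge_bp_pair,
    omop_to_fhir,
    pair_bp_rows,
)
from fhiromop.synthetic_data import generate_bp_observation, generate_single_vital

PATIENT_REF = ResourceReference(type="Patient", identifier=Identifier(system="s", value="p1"))


@pytest.fixture()
def temperature_row(ctx):
    obs = generate_single_vital(21, "8310-5", PATIENT_REF, identifier_value="OBS-T")
    return observation_to_measurement(obs, ctx)


@pytest.fixture()
def bp_rows(ctx):
    obs = generate_bp_observation(8, PATIENT_REF, identifier_value="OBS-BP")
    return observation_to_bp_rows(obs, ctx)


class TestMeasurementToObservation:
    def test_constants_final_and_vital_signs(self, temperature_row, ctx):
        obs = measurement_to_observation(temperature_row, ctx)
        assert obs.status == "final"
        assert any(c.has_code("vital-signs") for c in obs.category)

    def test_integer_key_becomes_string_identifier(self, ctx):
        row = MeasurementRow(
            measurement_id=12, person_id=3, measurement_concept_id=3020891, value_as_number=37.0
        )
        obs = measurement_to_observation(row, ctx)
        assert obs.id == "12"
        assert obs.subject.reference == "Patient/omop-person-3"
        assert obs.subject.type == "Patient"

    def test_reference_range_reconstructed(self, temperature_row, ctx):
        obs = measurement_to_observation(temperature_row, ctx)
        assert obs.referenceRange[0].low.value == 36.1
        assert obs.referenceRange[0].high.value == 38.0


class TestPairBpRows:
    def test_one_pair_no_leftovers(self, bp_rows, ctx):
        pairs, leftovers = pair_bp_rows(list(bp_rows), ctx)
        assert len(pairs) == 1 and leftovers == []

    def test_distinct_event_ids_do_not_pair(self, bp_rows, ctx):
        systolic, diastolic = bp_rows
        diastolic.measurement_event_id = "other-event"
        pairs, leftovers = pair_bp_rows([systolic, diastolic], ctx)
        assert pairs == [] and len(leftovers) == 2

    def test_empty_input(self, ctx):
        assert pair_bp_rows([], ctx) == ([], [])

    def test_two_systolic_rows_is_ambiguous(self, bp_rows, ctx):
        systolic, diastolic = bp_rows
        duplicate = MeasurementRow(**vars(systolic))
        with pytest.raises(AmbiguityError, match="systolic"):
            pair_bp_rows([systolic, duplicate, diastolic], ctx)

    def test_non_bp_rows_are_leftovers_not_dropped(self, temperature_row, bp_rows, ctx):
        pairs, leftovers = pair_bp_rows([temperature_row, *bp_rows], ctx)
        assert len(pairs) == 1 and leftovers == [temperature_row]


class TestMergeBpPair:
    def test_components_hold_both_values(self, bp_rows, ctx):
        pairs, _ = pair_bp_rows(list(bp_rows), ctx)
        merged = merge_bp_pair(pairs[0], ctx)
        values = sorted(c.valueQuantity.value for c in merged.component)
        expected = sorted([bp_rows[0].value_as_number, bp_rows[1].value_as_number])
        assert values == expected
        assert len(merged.component) == 2

    def test_no_top_level_value_and_no_text(self, bp_rows, ctx):
        pairs, _ = pair_bp_rows(list(bp_rows), ctx)
        merged = merge_bp_pair(pairs[0], ctx)
        assert merged.valueQuantity is None
        assert merged.code.text is None

    def test_merge_inverts_split_exactly(self, ctx):
        original = generate_bp_observation(77, PATIENT_REF, identifier_value="OBS-RT")
        rows = observation_to_bp_rows(original, ctx)
        pairs, _ = pair_bp_rows(list(rows), ctx)
        merged = merge_bp_pair(pairs[0], ctx)
        for code in ("8480-6", "8462-4"):
            assert (
                merged.component_by_code(code).valueQuantity.value
                == original.component_by_code(code).valueQuantity.value
            )
            assert merged.component_by_code(code).valueQuantity.code == "mm[Hg]"
        assert merged.effectiveDateTime == original.effectiveDateTime

    def test_shared_fields_come_from_the_systolic_row(self, bp_rows, ctx):
        pairs, _ = pair_bp_rows(list(bp_rows), ctx)
        merged = merge_bp_pair(pairs[0], ctx)
        assert merged.status == "final"
        assert merged.subject is not None


class TestOmopToFhir:
    def test_counts_pairs_merged_singles_converted(self, temperature_row, bp_rows, ctx):
        rowset = OmopRowSet(measurement=[temperature_row, *bp_rows], provenance="logical")
        observations, report = omop_to_fhir(rowset, ctx)
        assert len(observations) == 2 and report == []

    def test_empty_rowset(self, ctx):
        assert omop_to_fhir(OmopRowSet(), ctx) == ([], [])

    def test_unpaired_bp_row_reported(self, bp_rows, ctx):
        rowset = OmopRowSet(measurement=[bp_rows[0]], provenance="logical")
        observations, report = omop_to_fhir(rowset, ctx)
        assert observations == [] and len(report) == 1 and "unpaired" in report[0]

    def test_no_patient_resources_ever_produced(self, cohort, fresh_ctx):
        rowset, _ = transform_bundle(cohort, fresh_ctx)
        physical, _, _ = finalize_physical(rowset)
        observations, _ = omop_to_fhir(physical, fresh_ctx)
        assert observations
        assert {o.resourceType for o in observations} == {"Observation"}

    def test_deidentified_output_has_no_person_fields(self, cohort, fresh_ctx):
        """String scan: no name/telecom/address elements anywhere in the output."""
        rowset, _ = transform_bundle(cohort, fresh_ctx)
        physical, _, _ = finalize_physical(rowset)
        observations, _ = omop_to_fhir(physical, fresh_ctx)
        blob = json.dumps([json.loads(serialize_resource(o)) for o in observations])
        for forbidden in ('"name"', '"telecom"', '"address"', "PAT-", "Practitioner1"):
            assert forbidden not in blob

    def test_record_conservation(self, cohort, fresh_ctx):
        """Every measurement row lands in exactly one Observation or the report."""
        rowset, _ = transform_bundle(cohort, fresh_ctx)
        physical, _, _ = finalize_physical(rowset)
        observations, report = omop_to_fhir(physical, fresh_ctx)
        merged_pairs = sum(1 for o in observations if o.component)
        singles = sum(1 for o in observations if not o.component)
        assert 2 * merged_pairs + singles + len(report) == len(physical.measurement)
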
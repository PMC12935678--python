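"""Surrogate keys, link tables and de-identified finalization."""

import pytest
from hypothesis import given, settings, strategies as st

from fhiromop.errors import DanglingReferenceError, FhirOmopError
from fhiromop.fhir_model import FhirPatient, Identifier, ResourceReference
from fhiromop.forward_transform import transform_bundle
from fhiromop.key_management import (
    LinkRegistry,
    assign_surrogate_keys,
    business_identifier,
    finalize_physical,
    resolve_logical_reference,
)
from fhiromop.omop_model import MeasurementRow, OmopRowSet, PersonRow, table_schema, write_table


class TestBusinessIdentifier:
    def test_system_qualified_dialect(self):
        patient = FhirPatient(identifier=[Identifier(system="s", value="P1")])
        assert business_identifier(patient) == "s|P1"

    def test_falls_back_to_resource_id(self):
        assert business_identifier(FhirPatient(id="abc")) == "abc"

    def test_neither_present_raises(self):
        with pytest.raises(FhirOmopError):
            business_identifier(FhirPatient())


class TestResolveLogicalReference:
    def test_literal_reference(self):
        assert resolve_logical_reference(ResourceReference(reference="Patient/p1")) == (
            "person",
            "p1",
        )

    def test_logical_identifier_with_type(self):
        ref = ResourceReference(type="Encounter", identifier=Identifier(system="s", value="v"))
        assert resolve_logical_reference(ref) == ("visit_occurrence", "s|v")

    def test_typeless_logical_identifier_raises(self):
        ref = ResourceReference(identifier=Identifier(system="s", value="v"))
        with pytest.raises(FhirOmopError):
            resolve_logical_reference(ref)

    def test_reference_and_identifier_use_the_same_dialect(self):
        """Both spellings of one target must key the same link-table entry."""
        patient = FhirPatient(identifier=[Identifier(system="s", value="P1")])
        logical = ResourceReference(
            type="Patient", identifier=Identifier(system="s", value="P1")
        )
        assert resolve_logical_reference(logical)[1] == business_identifier(patient)


class TestAssignSurrogateKeys:
    def test_sequential_from_one(self):
        registry = assign_surrogate_keys(LinkRegistry(), "person", ["a", "b"])
        assert registry.table("person").entries == {"a": 1, "b": 2}

    def test_idempotent_reassignment(self):
        registry = assign_surrogate_keys(LinkRegistry(), "person", ["a", "b"])
        assign_surrogate_keys(registry, "person", ["a"])
        assert registry.table("person").entries["a"] == 1

    def test_duplicate_safe(self):
        registry = assign_surrogate_keys(LinkRegistry(), "person", ["a", "a", "b"])
        assert len(registry.table("person").entries) == 2

    def test_tables_keyed_independently(self):
        registry = LinkRegistry()
        assign_surrogate_keys(registry, "person", ["x"])
        assign_surrogate_keys(registry, "provider", ["y"])
        assert registry.table("person").entries["x"] == 1
        assert registry.table("provider").entries["y"] == 1

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.text(min_size=1, max_size=8)))
    def test_injective_and_idempotent_over_random_multisets(self, values):
        registry = assign_surrogate_keys(LinkRegistry(), "measurement", values)
        entries = registry.table("measurement").entries
        # injective both ways
        assert len(set(entries.values())) == len(entries)
        assert set(entries) == set(values)
        # idempotent: reassignment changes nothing
        before = dict(entries)
        assign_surrogate_keys(registry, "measurement", values)
        assert registry.table("measurement").entries == before
        # keys are 1..n
        assert sorted(entries.values()) == list(range(1, len(entries) + 1))


class TestFinalizePhysical:
    def make_rowset(self, subject="p1"):
        return OmopRowSet(
            person=[PersonRow(person_id="p1", person_source_value="p1")],
            measurement=[
                MeasurementRow(
                    measurement_id="m1",
                    person_id=subject,
                    measurement_concept_id=3020891,
                    measurement_source_value="m1",
                )
            ],
            provenance="logical",
        )

    def test_foreign_key_resolves_to_person_integer(self):
        physical, registry, warnings = finalize_physical(self.make_rowset())
        assert physical.person[0].person_id == 1
        assert physical.measurement[0].person_id == 1
        assert warnings == []

    def test_source_values_cleared_after_finalize(self):
        physical, _, _ = finalize_physical(self.make_rowset())
        assert physical.measurement[0].measurement_source_value is None
        assert physical.person[0].person_source_value is None

    def test_traceability_override_keeps_source_values(self):
        physical, _, _ = finalize_physical(self.make_rowset(), clear_source_values=False)
        assert physical.measurement[0].measurement_source_value == "m1"

    def test_dangling_reference_strict_raises_lenient_warns(self):
        with pytest.raises(DanglingReferenceError, match="px"):
            finalize_physical(self.make_rowset(subject="px"), strict=True)
        physical, _, warnings = finalize_physical(self.make_rowset(subject="px"), strict=False)
        assert physical.measurement[0].person_id is None
        assert len(warnings) == 1

    def test_stable_across_reruns(self):
        first, _, _ = finalize_physical(self.make_rowset())
        second, _, _ = finalize_physical(self.make_rowset())
        assert first == second


class TestCohortDeidentification:
    def test_bp_pair_shares_one_integer_event_key(self, cohort, fresh_ctx):
        rowset, _ = transform_bundle(cohort, fresh_ctx)
        physical, _, _ = finalize_physical(rowset)
        bp_rows = [r for r in physical.measurement if r.measurement_event_id is not None]
        assert bp_rows and len(bp_rows) % 2 == 0
        events = {}
        for row in bp_rows:
            assert isinstance(row.measurement_event_id, int)
            events.setdefault(row.measurement_event_id, []).append(row)
        assert all(len(group) == 2 for group in events.values())

    def test_no_business_identifier_in_physical_csvs(self, cohort, fresh_ctx):
        """Full-text de-identification scan over all five serialized tables."""
        rowset, _ = transform_bundle(cohort, fresh_ctx)
        physical, registry, _ = finalize_physical(rowset)
        csv_blob = "".join(
            write_table(physical.rows(name), table_schema(name))
            for name in ("care_site", "provider", "person", "visit_occurrence", "measurement")
        )
        identifiers = {
            value for table in registry.tables.values() for value in table.entries
        }
        assert identifiers
        for identifier in identifiers:
            assert identifier not in csv_blob

    def test_referential_integrity_of_finalized_cohort(self, cohort, fresh_ctx):
        rowset, _ = transform_bundle(cohort, fresh_ctx)
        physical, _, warnings = finalize_physical(rowset, strict=True)
        assert warnings == []
        person_ids = {r.person_id for r in physical.person}
        visit_ids = {r.visit_occurrence_id for r in physical.visit_occurrence}
        provider_ids = {r.provider_id for r in physical.provider}
        for row in physical.measurement:
            assert row.person_id in person_ids
            assert row.visit_occurrence_id in visit_ids
            assert row.provider_id in provider_ids
        for row in physical.visit_occurrence:
            assert row.person_id in person_ids


def test_link_table_csv_round_trip(tmp_path):
    from fhiromop.key_management import LinkTable

    table = LinkTable(table_name="person")
    table.assign("s|P1")
    table.assign("s|P2")
    path = tmp_path / "person_links.csv"
    table.to_csv(path)
    assert LinkTable.from_csv(path, "person").entries == table.entries
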
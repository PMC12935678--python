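# Methods

This note documents the transformation model the package implements, the
choices made where the design was genuinely open, what the synthetic
generator does and does not emulate, and the known limitations.

## The mapping model

The transformation treats FHIR → OMOP as a *column-level rule set*, not a
schema conversion. Each OMOP column is classified by how the rules populate
it:

* **direct** — value copied with compatible type and meaning
  (`value_as_number`, `range_low/high`, names, source-value strings);
* **indirect** — value derived via terminology translation
  (`measurement_concept_id`, `unit_concept_id`, …), key resolution
  (`person_id`, `visit_occurrence_id`, …) or lexical decomposition (the
  date/time/datetime triple, year/month/day of birth);
* **constant** — fixed by the transformation context
  (`meas_event_field_concept_id = 1147138`);
* **none** — not populatable from base FHIR resources.

Coverage statistics are computed from this declaration — what the rule set
*can* populate — rather than from data presence in any particular run, and a
separate audit (`coverage.audit_rowset`) checks that an actual transformed
rowset honors the declaration: no column populated outside its table's
declared set, no declared column left unexercised. One column,
`operator_concept_id`, is declared *conditional* in the audit: it is
populated only when the source Quantity carries a comparator, which is
legitimately rare, so its absence in a given rowset is not a defect.

The Measurement table is modelled in a 22-column working variant (CDM v5.4
without `visit_detail_id`) — the layout whose transformed/untransformed
arithmetic the coverage report is built on — with the full 23-column v5.4
layout selectable (`schema-variant: cdm54-full`). The other four tables are
the standard v5.4 column sets (Care Site 6, Provider 13, Person 18, Visit
Occurrence 17).

Four CDM-mandatory columns are never populated by the reusable rules:
`race_concept_id` and `ethnicity_concept_id` (Person), and
`visit_type_concept_id` / `measurement_type_concept_id` (record-origin
"type concepts"). Base FHIR resources carry none of this information. The
type concepts *can* be inferred in a deployment-specific run, so
`TransformContext.type_concepts` accepts overrides; the default leaves them
empty rather than guessing.

## Blood pressure: split and merge

FHIR stores systolic and diastolic pressure as two components of one
Observation; OMOP stores two Measurement rows. The transformation is
deliberately kept as two independent single-purpose rules (one per
component, selected by a conditional filter on LOINC 8480-6 / 8462-4), each
consuming one resource and emitting one row — the one-input/one-output
discipline every rule in the package follows, with `transform_bundle` as
pure orchestration.

Linkage contract: both rows carry the observation's business identifier in
`measurement_event_id` and `measurement_source_value`, and
`meas_event_field_concept_id = 1147138` (the standard concept meaning "the
event id originates from the measurement_id column"). A row is uniquely
identified by the combination (measurement_id, measurement_concept_id,
measurement_event_id). Because `measurement_id` must differ between the two
rows while the shared identifier must survive, the *logical* primary-key
source values are suffixed (`<business-id>|8480-6`, `<business-id>|8462-4`)
and the bare identifier keys the event. On finalization the event value is
issued its own integer from the measurement link table, so the pair shares
one group key; the referential-integrity check therefore treats
`measurement_event_id` as a group key, not a foreign key into the
measurement rows.

The reverse merge runs in two stages mirroring the split: rows are linked on
their event key (exactly one systolic + one diastolic concept; two same-side
rows raise an ambiguity error, unpaired rows are reported, never dropped),
each row is converted by the ordinary single-value rule, the two
intermediates are grouped in a `collection` Bundle, and the Bundle is folded
into one composite Observation. Shared elements (subject, encounter,
performer, effective time, status, category) are taken from the systolic
intermediate — the two sources agree on them by construction, but a
deterministic choice is required. The merged resource takes the panel code
(LOINC 85354-9) from a dedicated map entry, carries both values in
`Observation.component.value`, has no top-level value and no synthesized
human-readable text (text cannot be attributed to either component
unambiguously).

## Keys and de-identification

Business identifiers are normalized to `system|value` (first identifier;
resource id as fallback), and logical references resolve to the same
dialect, so a reference and the resource it targets key the same link-table
entry. Surrogate keys are sequential per-table integers starting at 1
(configurable offset for multi-source merges); assignment is idempotent and
duplicate-safe, so incremental loads reuse existing keys. Hash-derived keys
were rejected: string-to-integer hashing cannot guarantee uniqueness.

`finalize_physical` rewrites every key column to integers, clears the five
identifier-bearing `*_source_value` columns (the identifiers live on only in
the sidecar `links/<table>_links.csv` files, which belong in a separately
governed store), and checks referential integrity. In strict mode a dangling
foreign key is an error naming row and column; in lenient mode the key is
left empty with a warning — auto-assigning a key for a missing target would
fabricate referential integrity. A `clear_source_values=False` override
keeps identifiers for traceability-oriented deployments; the default clears
them, since source-value columns are excluded from standard analytics
anyway.

Reverse-direction references are assembled as `Type/omop-<table>-<key>` with
a constant `type` element: structurally valid FHIR, deliberately
non-functional, because reconnecting them to real identifiers would undo
de-identification. For the same reason no Patient, Encounter, Practitioner
or Organization resource is ever reconstructed — the elements a usable
Patient resource requires do not exist in the CDM.

## Terminology

Translation is ConceptMap-driven in both directions. Forward groups map
(system, code) → concept id; reverse groups map concept id → Coding with
system and display. Reverse entries are the *only* source of system/display
on reconstruction — the CDM does not record which terminology a concept came
from, so nothing is synthesized beyond what the map declares. Unmapped is a
result, not an error: the concept column stays empty and a warning is
logged, so partially mapped vocabularies degrade gracefully.

The shipped maps freeze OHDSI concept ids compiled once from the public
OHDSI vocabulary (gender 8507/8532, visit classes 9201/9202/9203, UCUM
units, operators, the eleven vital-sign LOINC entries). They are fixtures
for a working default pipeline, not a vocabulary distribution; a site
replaces them by pointing `--maps` at a directory with the same filenames.

## Dates and numbers

* Numeric values (`value_as_number`, `range_low/high`) are copied exactly —
  no rounding anywhere in either direction.
* `split_effective` keeps the verbatim lexical form of a dateTime in
  `measurement_datetime` (timezone included), which is what makes the
  round trip exact; the date and clock parts are substrings of it. A
  date-only value yields an empty time and a midnight datetime. Year-only
  and year-month forms are rejected rather than silently padded: a
  Measurement date would be an invention.
* CSV: RFC-4180, ISO-8601 dates/times, empty string for NULL. Decimals that
  are integral print without a trailing `.0` so physical CSVs are stable
  across read/write cycles.

## Synthetic cohorts

The generator emulates a small outpatient vital-signs extract: one
organization, a two-practitioner pool, `n_patients` patients (default 5)
with one encounter each plus one chained follow-up encounter, and
`observations_per_patient` (default 4) observations allocated over the nine
vital-sign types by largest-remainder apportionment of the mix weights and
then shuffled — so the default uniform mix exercises every type (and both
blood-pressure components) whenever the cohort has ≥ 9 observations. All
cross-references are logical (identifier-based) and resolve within the
cohort; every emitted code, unit and comparator is covered by the shipped
maps. The seed fully determines the output.

Value distributions are conventional physiologic choices, documented here
because no external dataset fixes them: temperature ~N(37.0, 0.5) °C,
respiratory rate ~N(16, 3) /min, heart rate ~N(75, 12) /min, SpO₂
~N(97, 1.5) % capped at 100, weight ~N(75, 12) kg, height ~N(170, 10) cm,
head circumference ~N(56, 2) cm, BMI ~N(24, 3.5) kg/m², systolic
~N(120, 15) and diastolic ~N(80, 10) mmHg with diastolic forced at least
10 mmHg below systolic. Reference ranges are fixed textbook intervals per
type. An oxygen-saturation reading carries a `>=` comparator with
probability `comparator_rate` (default 0.1); missingness knobs (encounter,
performer, reference range) default to 0.

What a green test on this cohort does **not** establish: robustness to
real-world EHR data (contained resources, profiles/extensions with meaning,
multiple identifiers per resource, non-LOINC codings, free-text units,
longitudinal visit structure) or terminology coverage beyond the shipped
inventory. The generator is a stand-in for hand-written example instances,
not a population model.

## Known limitations

* Qualitative observations are classified `unsupported`; routing them to the
  CDM Observation table is out of scope.
* Reverse reconstruction is inherently lossy: status/category are constants,
  references are non-functional, and original code systems/display texts
  are recoverable only through the concept maps. No reverse-direction
  coverage percentage is computed — with no fixed mandatory element set on
  the FHIR side there is no defensible column-level denominator.
* One provider per Measurement: when an Observation lists several
  performers, the first Practitioner-typed reference wins; Organization
  performers are ignored with a warning (Measurement has no care-site link).
* Concept ids in the shipped maps are frozen fixtures; deployments should
  regenerate them against their vocabulary version.
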
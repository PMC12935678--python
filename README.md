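# fhiromop

Bidirectional, rule-based transformation of **vital-signs data** between HL7
FHIR resources and OMOP CDM v5.4 tables, for health-informatics engineers
building secondary-use (research) pipelines on top of clinical FHIR data.

Clinical care systems exchange data as FHIR resources; observational research
runs on the OMOP Common Data Model. The two serve different purposes — FHIR
is rich, hierarchical and identifier-laden; OMOP is a fixed, de-identified
relational schema — so moving data between them is a rule-by-rule mapping
problem, not a format conversion. This package implements that mapping for
the vital-signs use case:

* **Forward (FHIR → OMOP)** — five resource/table rules: Observation →
  Measurement, Patient → Person, Encounter → Visit Occurrence, Practitioner →
  Provider, Organization → Care Site. Composite blood pressure is split by
  two component rules keyed on LOINC 8480-6 (systolic) and 8462-4
  (diastolic): one Observation becomes two Measurement rows sharing a
  `measurement_event_id`, with `meas_event_field_concept_id = 1147138`
  marking where the event key originates.
* **Terminology** — all coded elements go through FHIR ConceptMap documents
  (`translate` / `reverse_translate`); an unmapped code leaves the concept
  column empty with a warning, never fails the row. The shipped maps cover
  the vital-sign LOINC codes, UCUM units, quantity comparators,
  administrative gender, encounter class and place-of-service codes.
* **Keys and de-identification** — FHIR business identifiers never enter the
  CDM. A per-table link table assigns sequential surrogate integers
  (injective, idempotent, duplicate-safe); finalization rewrites all keys to
  integers, clears identifier-bearing `*_source_value` columns and keeps the
  link tables as sidecar CSVs outside the CDM output.
* **Reverse (OMOP → FHIR)** — Measurement rows become Observation resources
  with fixed defaults (`status = "final"`, vital-signs category) and
  structurally valid but non-functional references built from the integer
  keys. Blood-pressure pairs are linked on their event key, converted to two
  intermediate Observations, grouped in a Bundle and merged into one
  composite resource. Patient-identifying resources are never reconstructed.
* **Coverage** — a declarative mapping specification classifies every column
  (direct / indirect / constant / none) and yields per-table completeness:
  Care Site 5/6 (83%), Provider 7/13 (54%), Person 11/18 (61%), Visit
  Occurrence 15/17 (88%), Measurement 18/22 (82%), 56/76 = **74%** overall,
  with exactly four mandatory columns untransformed (race, ethnicity, visit
  and measurement type concepts — information base FHIR resources do not
  carry).
* **Synthetic cohorts** — a seeded generator produces internally consistent
  cohorts (Organization, Practitioners, Patients, Encounters, all nine
  vital-sign types) whose references resolve in-cohort and whose codes are
  fully covered by the shipped maps.

## Worked example

```bash
$ fhiromop synth --seed 7 --out cohort.json
synth: wrote 34 resources to cohort.json

$ fhiromop fhir2omop --in cohort.json --out omop --strict --report report.json
fhir2omop: 34 resources -> care_site=1, provider=2, person=5, visit_occurrence=6, measurement=22; 0 error(s), 0 warning(s)

$ fhiromop omop2fhir --in omop --out reconstructed.json
omop2fhir: 22 measurement rows -> 20 Observations; 0 issue(s)
```

The cohort holds 5 patients × 4 observations = 20 Observations; 2 of them
are blood-pressure panels, so the Measurement table gets 22 rows (each panel
splits into a systolic and a diastolic record), and the reverse run merges
those pairs back into 20 Observations. A follow-up Encounter for the first
patient makes 6 visits for 5 patients. `omop/` holds the five de-identified
CSVs plus `links/<table>_links.csv`; `report.json` records per-resource
errors, warnings, the column audit and the coverage summary.

```bash
$ fhiromop coverage
OMOP CDM table      Transformed/total  Untransformed mandatory  Percent
Care Site                         5/6                        0      83%
Provider                         7/13                        0      54%
Person                          11/18                        2      61%
Visit Occurrence                15/17                        1      88%
Measurement                     18/22                        1      82%
Overall                                                             74%
```

Percentages are transformed/total columns rounded half-up; "untransformed
mandatory" counts CDM-mandatory columns the rules cannot populate from base
FHIR resources.

The same pipeline is available as a library:

```python
from fhiromop.forward_transform import TransformContext, transform_bundle
from fhiromop.key_management import finalize_physical
from fhiromop.reverse_transform import omop_to_fhir
from fhiromop.synthetic_data import CohortConfig, generate_cohort

ctx = TransformContext.default()
rowset, errors = transform_bundle(generate_cohort(CohortConfig(seed=7)), ctx)
physical, registry, warnings = finalize_physical(rowset, strict=True)
observations, issues = omop_to_fhir(physical, ctx)
```

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch — seeded
cohort generation, forward transform, strict surrogate-key finalization,
reverse reconstruction and the coverage report — logging each stage to
stderr and writing the results JSON to `--out`:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| Module | Role |
| --- | --- |
| `fhiromop.fhir_model` | typed FHIR resources, JSON parse/serialize, minimal validity |
| `fhiromop.omop_model` | CDM table schemas (22-column working / full v5.4 Measurement variants), row types, CSV I/O |
| `fhiromop.concept_maps` | ConceptMap loading, forward/reverse translation, shipped `maps/` |
| `fhiromop.forward_transform` | FHIR → OMOP rules incl. the blood-pressure split |
| `fhiromop.reverse_transform` | OMOP → FHIR reconstruction incl. the Bundle-based merge |
| `fhiromop.key_management` | business identifiers, link tables, de-identified finalization |
| `fhiromop.coverage` | mapping spec, completeness report, rowset audit |
| `fhiromop.synthetic_data` | seeded cohort generator |
| `fhiromop.cli` | `fhiromop` command: `fhir2omop`, `omop2fhir`, `coverage`, `synth` |

See `docs/methods.md` for the transformation model, its assumptions and
known limitations.
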
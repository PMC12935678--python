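"""ConceptMap loading and bidirectional code <-> OHDSI concept-id translation.

Terminology translation is deliberately partial: an unmapped code is a
*result*, never an error, and callers leave the target concept column empty
(mirroring concept columns that are only partially populated in practice).
The shipped maps under ``maps/`` are FHIR-ConceptMap-JSON documents whose
OHDSI concept ids were compiled once from the public OHDSI vocabulary and
frozen in-repo; each entry carries its display term as documentation.

A map may declare *forward* groups (source terminology -> OHDSI) and
*reverse* groups (OHDSI -> a terminology).  Reverse entries are the only
source of system/display on reconstruction — no free-text synthesis, because
the original terminology system of a stored concept id is unknowable from
the CDM side alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from fhiromop.errors import FhirOmopError
from fhiromop.fhir_model import Coding

__all__ = [
    "OHDSI_SYSTEM",
    "ROLE_FILES",
    "ConceptMap",
    "TranslateResult",
    "load_concept_map",
    "load_shipped_maps",
    "translate",
    "reverse_translate",
]

#: Label/URI standing for the OHDSI standardized vocabularies as a ConceptMap
#: "system".  Groups with this source are reverse (concept-id -> Coding) groups.
OHDSI_SYSTEM = "https://athena.ohdsi.org"

#: Shipped map file per transformation role.
ROLE_FILES = {
    "code": "vital-signs-loinc.json",
    "unit": "ucum-units.json",
    "operator": "quantity-comparator.json",
    "gender": "administrative-gender.json",
    "class": "encounter-class.json",
    "place-of-service": "place-of-service.json",
}


@dataclass
class TranslateResult:
    outcome: str  # "mapped" | "unmapped"
    concept_id: Optional[int] = None
    coding: Optional[Coding] = None
    display: Optional[str] = None

    @property
    def mapped(self) -> bool:
        return self.outcome == "mapped"


UNMAPPED = TranslateResult(outcome="unmapped")


@dataclass
class ConceptMap:
    """Code-system-qualified code <-> OHDSI concept-id lookup."""

    map_id: str
    forward: dict[tuple[str, str], tuple[int, Optional[str]]] = field(default_factory=dict)
    reverse: dict[int, Coding] = field(default_factory=dict)

    def forward_codes(self) -> list[tuple[str, str]]:
        return list(self.forward)


def _load_payload(source: Union[str, Path, dict]) -> dict:
    if isinstance(source, dict):
        return source
    text = Path(source).read_text(encoding="utf-8")
    return json.loads(text)


def load_concept_map(source: Union[str, Path, dict]) -> ConceptMap:
    """Load a FHIR-ConceptMap-JSON document (group/element/target structure).

    Raises :class:`FhirOmopError` when one source code (or one concept id in
    a reverse group) is given two conflicting targets.
    """
    payload = _load_payload(source)
    if payload.get("resourceType") not in (None, "ConceptMap"):
        raise FhirOmopError(f"not a ConceptMap: resourceType={payload.get('resourceType')!r}")
    cmap = ConceptMap(map_id=payload.get("id", "concept-map"))
    for group in payload.get("group", []):
        src_system = group.get("source", "")
        tgt_system = group.get("target", "")
        for element in group.get("element", []):
            code = element.get("code")
            targets = element.get("target", [])
            if code is None or not targets:
                continue
            if len(targets) > 1:
                raise FhirOmopError(
                    f"map {cmap.map_id}: code {code!r} has {len(targets)} targets; "
                    "exactly one is allowed"
                )
            target = targets[0]
            if src_system == OHDSI_SYSTEM:
                concept_id = int(code)
                coding = Coding(
                    system=tgt_system, code=target.get("code"), display=target.get("display")
                )
                existing = cmap.reverse.get(concept_id)
                if existing is not None and existing != coding:
                    raise FhirOmopError(
                        f"map {cmap.map_id}: concept id {concept_id} has conflicting "
                        "reverse targets"
                    )
                cmap.reverse[concept_id] = coding
            else:
                key = (src_system, code)
                entry = (int(target["code"]), target.get("display"))
                existing_fwd = cmap.forward.get(key)
                if existing_fwd is not None and existing_fwd != entry:
                    raise FhirOmopError(
                        f"map {cmap.map_id}: code {code!r} has conflicting targets"
                    )
                cmap.forward[key] = entry
    return cmap


def load_shipped_maps(directory: Union[str, Path, None] = None) -> dict[str, ConceptMap]:
    """Load the per-role concept maps shipped with the package.

    ``directory`` overrides the bundled ``maps/`` directory (same filenames
    expected), so site-specific vocabularies can be dropped in.
    """
    maps: dict[str, ConceptMap] = {}
    for role, filename in ROLE_FILES.items():
        if directory is not None:
            maps[role] = load_concept_map(Path(directory) / filename)
        else:
            ref = resources.files("fhiromop") / "maps" / filename
            maps[role] = load_concept_map(json.loads(ref.read_text(encoding="utf-8")))
    return maps


def translate(code: str, system: Optional[str], cmap: ConceptMap) -> TranslateResult:
    """Forward-translate a (system, code) pair to an OHDSI concept id.

    With ``system=None`` the code matches on code alone provided it is
    unambiguous across the map's systems.  Unmapped codes return an unmapped
    result; they never raise.
    """
    if system is not None:
        entry = cmap.forward.get((system, code))
        if entry is None:
            return UNMAPPED
        return TranslateResult(outcome="mapped", concept_id=entry[0], display=entry[1])
    hits = [entry for (sys_, c), entry in cmap.forward.items() if c == code]
    if len(hits) != 1 or len({h[0] for h in hits}) != 1:
        return UNMAPPED
    return TranslateResult(outcome="mapped", concept_id=hits[0][0], display=hits[0][1])


def reverse_translate(concept_id: Optional[int], cmap: ConceptMap) -> TranslateResult:
    """Reverse-translate an OHDSI concept id to a Coding (system + code).

    Display is populated only when the reverse entry carries one.  Missing
    ids return an unmapped result.
    """
    if concept_id is None:
        return UNMAPPED
    coding = cmap.reverse.get(int(concept_id))
    if coding is None:
        return UNMAPPED
    return TranslateResult(
        outcome="mapped",
        concept_id=int(concept_id),
        coding=coding.model_copy(deep=True),
        display=coding.display,
    )
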
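"""Concept-to-category projection: the pathway-building stages.

Each recognized concept is projected to ICD-10 codes with a
Restrict-to-ICD10 style rule (direct crosswalk entries first, then the
nearest mapped ancestors), and the codes are projected onward to GBD
categories under the unique-inclusion rule.  Concepts with no automatic
route may be rescued by the expert enrichment table.  Every complete
route (field -> concept -> code -> category) is recorded as a
:class:`Pathway`, the unit over which the prioritization rules operate
and the audit trail a reviewer can inspect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Optional, Union

from .annotation import FIELD_NAMES, Annotation
from .lexicon import EnrichmentTable, Lexicon
from .taxonomy import GBDGrouping, ICD10Spec, parse_icd10, project_spec

if TYPE_CHECKING:  # pragma: no cover
    from .classifier import TrialRecord


class ProjectionError(KeyError):
    """Lookup of an unknown concept."""


@dataclass(frozen=True)
class Pathway:
    """One traced route from a trial field to a candidate GBD category.

    ``icd10`` is ``None`` exactly when the route went through the
    enrichment table instead of the crosswalk.
    """

    trial_id: str
    field_name: str
    cui: str
    icd10: Optional[ICD10Spec]
    category_id: str
    via_enrichment: bool = False


def restrict_to_icd10(cui: str, lexicon: Lexicon) -> tuple[ICD10Spec, ...]:
    """Project a concept to ICD-10 codes/blocks.

    Step 1: the concept's own crosswalk entries.  Step 2 (only if step 1
    is empty): ascend the hierarchy breadth-first and return the union
    of crosswalk entries at the first (shallowest) depth where any
    ancestor is mapped.  Returns an empty tuple when no ancestor is
    mapped anywhere.
    """
    if cui not in lexicon.concepts:
        raise ProjectionError(f"unknown cui {cui!r}")
    direct = lexicon.crosswalk.get(cui)
    if direct:
        return direct
    seen = {cui}
    frontier = sorted(lexicon.parents.get(cui, ()))
    while frontier:
        found: list[ICD10Spec] = []
        for ancestor in frontier:
            for spec in lexicon.crosswalk.get(ancestor, ()):
                if spec not in found:
                    found.append(spec)
        if found:
            return tuple(found)
        seen.update(frontier)
        frontier = sorted(
            {p for node in frontier for p in lexicon.parents.get(node, ()) if p not in seen}
        )
    return ()


def concept_to_categories(
    cui: str,
    lexicon: Lexicon,
    grouping: GBDGrouping,
    enrichment: Optional[EnrichmentTable] = None,
) -> set[tuple[str, bool]]:
    """All (category_id, via_enrichment) pairs a concept reaches.

    Automatic routes (crosswalk + code projection) always win; the
    enrichment table is consulted only when they yield nothing.
    """
    cats: set[tuple[str, bool]] = set()
    for spec in restrict_to_icd10(cui, lexicon):
        for cat in project_spec(spec, grouping):
            cats.add((cat.id, False))
    if not cats and enrichment is not None and cui in enrichment:
        cats = {(cid, True) for cid in enrichment.entries[cui]}
    return cats


def build_pathways(
    trial: "TrialRecord",
    annotations: dict[str, list[Annotation]],
    lexicon: Lexicon,
    grouping: GBDGrouping,
    enrichment: Optional[EnrichmentTable] = None,
) -> list[Pathway]:
    """Derive every pathway from a trial's annotations, duplicates collapsed.

    One pathway per distinct (field, cui, icd10 spec, category)
    combination; enrichment pathways carry no ICD-10 spec.  Output is
    deterministically ordered (field order, then cui, spec, category).
    """
    found: set[Pathway] = set()
    for field_name in FIELD_NAMES:
        cuis = sorted({ann.cui for ann in annotations.get(field_name, ())})
        for cui in cuis:
            automatic = False
            for spec in restrict_to_icd10(cui, lexicon):
                for cat in project_spec(spec, grouping):
                    automatic = True
                    found.add(Pathway(trial.trial_id, field_name, cui, spec, cat.id, False))
            if not automatic and enrichment is not None and cui in enrichment:
                for cid in sorted(enrichment.entries[cui]):
                    found.add(Pathway(trial.trial_id, field_name, cui, None, cid, True))
    order = {name: i for i, name in enumerate(FIELD_NAMES)}
    return sorted(
        found,
        key=lambda p: (order[p.field_name], p.cui, "" if p.icd10 is None else str(p.icd10), p.category_id),
    )


def write_trace(pathways: list[Pathway], path: Union[str, Path]) -> None:
    """Append-free JSON-lines dump of pathways for audit."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in pathways:
            fh.write(
                json.dumps(
                    {
                        "trial_id": p.trial_id,
                        "field": p.field_name,
                        "cui": p.cui,
                        "icd10": None if p.icd10 is None else str(p.icd10),
                        "category_id": p.category_id,
                        "via_enrichment": p.via_enrichment,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_trace(path: Union[str, Path]) -> list[Pathway]:
    out = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                Pathway(
                    rec["trial_id"],
                    rec["field"],
                    rec["cui"],
                    None if rec["icd10"] is None else parse_icd10(rec["icd10"]),
                    rec["category_id"],
                    rec["via_enrichment"],
                )
            )
    return out
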
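"""Trial classification: prioritization over pathways, variants, baseline.

The final stage of the pipeline turns the set of pathways derived for a
trial into its (possibly multi-label) GBD classification.  Two
prioritization rules apply:

1. *Field priority* (optional): the health-condition field is, by
   definition, where registrants describe the condition studied, so when
   it yields any candidate category, pathways from the titles are
   discarded.  When the condition field yields nothing (empty, entry
   errors, "Healthy volunteers"), title pathways are used as fallback.
2. *Multiplicity*: a category consistently reached by several distinct
   (concept, ICD-10 code) supports beats categories reached by isolated
   pathways, which are likely noise.  Concretely, if any candidate has
   at least two supports, candidates with a single support are dropped.

A trial whose retained candidate set is empty is a "No GBD" trial:
either its condition belongs to a residual category or it is not a
disease at all (e.g. pain management, healthy volunteers).

The three switches — WSD on/off, enrichment on/off, field priority
on/off — form the 2x2x2 grid of eight classifier variants.

A verbatim-match baseline is included for comparison: a trial is
assigned a category iff one of the disease names defining that category
appears verbatim (case-insensitive, word-bounded) in the selected text
fields.
"""

from __future__ import annotations

import csv
import itertools
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .annotation import FIELD_NAMES, Annotation, annotate, validate_spans
from .lexicon import EnrichmentTable, Lexicon
from .projection import Pathway, build_pathways
from .taxonomy import GBDGrouping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialRecord:
    """One registered trial: id plus the three free-text fields."""

    trial_id: str
    condition: str = ""
    public_title: str = ""
    scientific_title: str = ""

    def __post_init__(self) -> None:
        if not self.trial_id:
            raise ValueError("trial_id must be non-empty")

    def field_text(self, field_name: str) -> str:
        return getattr(self, field_name)


@dataclass(frozen=True)
class ClassifierConfig:
    """The three binary switches of the classifier."""

    wsd: bool = False
    enrichment: bool = False
    field_priority: bool = False

    def label(self) -> str:
        return f"wsd{int(self.wsd)}_enrich{int(self.enrichment)}_priority{int(self.field_priority)}"


#: The 2x2x2 grid of classifier variants.
ALL_VARIANTS: tuple[ClassifierConfig, ...] = tuple(
    ClassifierConfig(w, e, p) for w, e, p in itertools.product((True, False), repeat=3)
)

#: The best-performing combination: WSD + enrichment + field priority.
BEST_VARIANT = ClassifierConfig(wsd=True, enrichment=True, field_priority=True)


@dataclass(frozen=True)
class Classification:
    """The classifier's output for one trial; no_gbd iff no category kept."""

    trial_id: str
    categories: frozenset[str]
    trace: tuple[Pathway, ...] = ()

    @property
    def no_gbd(self) -> bool:
        return not self.categories


def prioritize(pathways: Sequence[Pathway], field_priority: bool = False) -> set[str]:
    """Apply the prioritization rules to one trial's pathways.

    Support for a category = number of distinct (cui, icd10) pairs among
    the retained pathways reaching it (an enrichment route counts as the
    single pair (cui, None)).
    """
    if not pathways:
        return set()
    pool = list(pathways)
    if field_priority:
        condition_pool = [p for p in pool if p.field_name == "condition"]
        if condition_pool:
            pool = condition_pool
    supports: dict[str, set[tuple[str, Optional[str]]]] = {}
    for p in pool:
        key = (p.cui, None if p.icd10 is None else str(p.icd10))
        supports.setdefault(p.category_id, set()).add(key)
    scores = {cid: len(s) for cid, s in supports.items()}
    m = max(scores.values())
    if m >= 2:
        return {cid for cid, s in scores.items() if s >= 2}
    return set(scores)


def classify_trial(
    trial: TrialRecord,
    lexicon: Lexicon,
    grouping: GBDGrouping,
    enrichment: Optional[EnrichmentTable] = None,
    config: ClassifierConfig = ClassifierConfig(),
    annotations: Optional[dict[str, list[Annotation]]] = None,
) -> Classification:
    """Run the full five-stage pipeline on one trial.

    ``annotations`` may supply externally produced concept mentions
    (keyed by field name) in place of the built-in matcher; spans are
    validated against the trial's field texts.
    """
    if annotations is None:
        annotations = {
            name: annotate(name, trial.field_text(name), lexicon, wsd=config.wsd)
            for name in FIELD_NAMES
        }
    else:
        for name, anns in annotations.items():
            validate_spans(anns, trial.field_text(name))
    pathways = build_pathways(
        trial,
        annotations,
        lexicon,
        grouping,
        enrichment=enrichment if config.enrichment else None,
    )
    categories = prioritize(pathways, field_priority=config.field_priority)
    return Classification(trial.trial_id, frozenset(categories), tuple(pathways))


def classify_batch(
    trials: Iterable[TrialRecord],
    lexicon: Lexicon,
    grouping: GBDGrouping,
    enrichment: Optional[EnrichmentTable] = None,
    config: ClassifierConfig = ClassifierConfig(),
    annotations: Optional[dict[str, dict[str, list[Annotation]]]] = None,
) -> list[Classification]:
    """Order-preserving map of :func:`classify_trial` over a corpus.

    A failing record is logged and skipped; the batch never aborts.
    """
    out: list[Classification] = []
    for trial in trials:
        try:
            trial_ann = None if annotations is None else annotations.get(trial.trial_id, {})
            out.append(
                classify_trial(trial, lexicon, grouping, enrichment, config, annotations=trial_ann)
            )
        except Exception:
            logger.exception("skipping trial %r: classification failed", getattr(trial, "trial_id", "?"))
    return out


# --- verbatim-match baseline -------------------------------------------------

NameIndex = dict[str, list[str]]

_FIELD_SELECTORS = {
    "condition": ("condition",),
    "public": ("public_title",),
    "scientific": ("scientific_title",),
    "all": FIELD_NAMES,
}


def load_name_index(path: Union[str, Path]) -> NameIndex:
    """Load the defining disease names per category (TSV: category_id, name)."""
    index: NameIndex = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not reader.fieldnames or not {"category_id", "name"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected columns category_id, name")
        for row in reader:
            cid = (row["category_id"] or "").strip()
            name = (row["name"] or "").strip()
            if cid and name:
                index.setdefault(cid, []).append(name)
    return index


def packaged_name_index() -> NameIndex:
    """Defining names of the shipped 28-class grouping's categories."""
    with resources.as_file(resources.files("gbdmap").joinpath("data/gbd28_names.tsv")) as p:
        return load_name_index(p)


def _name_pattern(name: str) -> re.Pattern:
    words = [re.escape(w) for w in name.split()]
    return re.compile(r"\b" + r"\W+".join(words) + r"\b", re.IGNORECASE)


def baseline_classify(
    trial: TrialRecord,
    name_index: NameIndex,
    fields: Union[str, Sequence[str]] = "all",
) -> set[str]:
    """Verbatim containment baseline: no knowledge source, just name matching."""
    if isinstance(fields, str):
        try:
            selected = _FIELD_SELECTORS[fields]
        except KeyError:
            raise ValueError(f"unknown field selector {fields!r}") from None
    else:
        selected = tuple(fields)
        for f in selected:
            if f not in FIELD_NAMES:
                raise ValueError(f"unknown field name {f!r}")
    texts = [trial.field_text(f) for f in selected]
    hits: set[str] = set()
    for cid, names in name_index.items():
        for name in names:
            pat = _name_pattern(name)
            if any(pat.search(t) for t in texts):
                hits.add(cid)
                break
    return hits
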
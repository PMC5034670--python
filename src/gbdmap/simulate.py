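"""Synthetic corpora for end-to-end testing without licensed resources.

The generator emits a self-consistent bundle — a mini-lexicon, a GBD
grouping, a trial corpus and its gold labels — in exactly the file
formats the rest of the package reads.  Each synthetic category owns a
disjoint ICD-10 letter range, every concept's crosswalk lands inside its
own category's range, and trial texts are templated from the category's
terms, so on an unperturbed bundle with ``p_ambiguous_term=0`` every
classifier variant recovers the gold labels exactly.  Gold labels are
assigned at generation time, never re-derived, so classifier bugs cannot
silently redefine truth.

The knobs emulate the pathologies of real registry records: empty
condition fields, condition fields that defer to the titles, "Healthy
volunteers" entries, terms shared by concepts of different categories
(exercising disambiguation and the multiplicity rule), multi-category
trials, and concepts reachable only through the expert enrichment table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .annotation import normalize_term
from .classifier import TrialRecord
from .evaluation import GoldLabel, save_gold
from .lexicon import (
    Concept,
    EnrichmentTable,
    Lexicon,
    load_enrichment,
    load_lexicon,
    save_enrichment,
    save_lexicon,
)
from .taxonomy import GBDCategory, GBDGrouping, load_grouping, parse_icd10, save_grouping

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

#: semantic type given to every synthetic disorder concept
_DISORDER_TYPE = "T047"


class GenerationError(ValueError):
    """The fixture specification is infeasible."""


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic corpus.

    Probabilities select mutually compatible trial pathologies; counts
    size the lexicon and corpus.  ``p_enrichment_only`` is the chance a
    trial's sole route to its gold category runs through the enrichment
    table (0 by default, so that every variant — including those with
    enrichment off — can recover the gold labels on a clean bundle).
    """

    n_trials: int = 200
    n_categories: int = 6
    terms_per_category: int = 4
    p_empty_condition: float = 0.1
    p_title_only: float = 0.05
    p_healthy_volunteer: float = 0.05
    p_ambiguous_term: float = 0.05
    p_multi_label: float = 0.05
    p_enrichment_only: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0 or self.n_categories <= 0 or self.terms_per_category <= 0:
            raise GenerationError("counts must be positive")
        if self.n_categories > len(_LETTERS):
            raise GenerationError(
                f"n_categories={self.n_categories} exceeds the {len(_LETTERS)} available letter ranges"
            )
        if self.terms_per_category > 80:
            raise GenerationError("terms_per_category exceeds the 80 majors reserved per category")
        for name in (
            "p_empty_condition",
            "p_title_only",
            "p_healthy_volunteer",
            "p_ambiguous_term",
            "p_multi_label",
            "p_enrichment_only",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise GenerationError(f"{name}={p} outside [0, 1]")


@dataclass
class Bundle:
    """A generated corpus plus every file it was written to."""

    root: Path
    lexicon_dir: Path
    grouping_path: Path
    trials_path: Path
    gold_path: Path
    enrichment_path: Path
    lexicon: Lexicon
    grouping: GBDGrouping
    enrichment: EnrichmentTable
    trials: list[TrialRecord]
    gold: list[GoldLabel]


def _pseudoword(rng: np.random.Generator, used: set[str], n_syllables: int = 3) -> str:
    while True:
        word = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syllables)
        )
        if word not in used:
            used.add(word)
            return word


@dataclass
class _SynthCategory:
    category: GBDCategory
    letter: str
    # terms usable in trial text, each with the cuis they resolve to and two codes
    trial_terms: list[str] = field(default_factory=list)
    ambiguous_term: Optional[str] = None
    ambiguous_partner_cat: Optional[str] = None
    enrichment_term: Optional[str] = None


def generate_bundle(spec: FixtureSpec, out_dir: Union[str, Path]) -> Bundle:
    """Generate, write and reload a fully self-consistent bundle.

    Everything is derived from ``spec.seed``; the same spec written
    twice produces byte-identical files.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    lexicon_dir = out_dir / "lexicon"
    out_dir.mkdir(parents=True, exist_ok=True)

    used_words: set[str] = set()
    concepts: dict[str, Concept] = {}
    terms: dict[str, set[str]] = {}
    parents: dict[str, set[str]] = {}
    crosswalk: dict[str, tuple] = {}
    enrichment_entries: dict[str, set[str]] = {}
    cats: list[_SynthCategory] = []
    cui_counter = 0

    def new_cui() -> str:
        nonlocal cui_counter
        cui_counter += 1
        return f"C{cui_counter:07d}"

    def add_concept(name: str, term_list: Sequence[str], specs: Sequence[str]) -> str:
        cui = new_cui()
        concepts[cui] = Concept(cui, name, frozenset({_DISORDER_TYPE}))
        for t in term_list:
            terms.setdefault(normalize_term(t), set()).add(cui)
        if specs:
            crosswalk[cui] = tuple(parse_icd10(s) for s in specs)
        return cui

    for i in range(spec.n_categories):
        letter = _LETTERS[i]
        word = _pseudoword(rng, used_words)
        cat = GBDCategory(f"cat_{letter.lower()}", f"Synthetic {word} disorders")
        syn = _SynthCategory(cat, letter)
        for j in range(spec.terms_per_category):
            term = f"{_pseudoword(rng, used_words)} {_pseudoword(rng, used_words, 2)}itis"
            codes = (f"{letter}{j:02d}", f"{letter}{j:02d}.9")
            if spec.terms_per_category >= 4 and j % 4 == 3:
                # crosswalk-free child concept: codes live on a synthetic parent,
                # exercising the hierarchy-ascent fallback
                parent_cui = add_concept(f"{term} group".title(), (), codes)
                child_cui = add_concept(term.title(), (term,), ())
                parents.setdefault(child_cui, set()).add(parent_cui)
            else:
                add_concept(term.title(), (term,), codes)
            syn.trial_terms.append(term)
        # enrichment-only concept: no crosswalk, no mapped ancestry
        e_term = f"{_pseudoword(rng, used_words)} {_pseudoword(rng, used_words, 2)}osis"
        e_cui = add_concept(e_term.title(), (e_term,), ())
        enrichment_entries[e_cui] = {cat.id}
        syn.enrichment_term = e_term
        cats.append(syn)

    # ambiguous terms: one shared term per category pair (cat i, cat i+1)
    if spec.n_categories >= 2:
        for i, syn in enumerate(cats):
            partner = cats[(i + 1) % spec.n_categories]
            amb = f"{_pseudoword(rng, used_words)} syndrome"
            # own-category sense: preferred name equals the term, single code,
            # smaller cui -> both WSD criteria favor the gold sense
            add_concept(amb.title(), (amb,), (f"{syn.letter}90",))
            add_concept(
                f"{_pseudoword(rng, used_words).title()} Variant Syndrome",
                (amb,),
                (f"{partner.letter}91",),
            )
            syn.ambiguous_term = amb
            syn.ambiguous_partner_cat = partner.category.id

    grouping = GBDGrouping(
        "synthetic",
        [c.category for c in cats],
        {c.category.id: [parse_icd10(f"{c.letter}00-{c.letter}99.9")] for c in cats},
    )

    trials: list[TrialRecord] = []
    gold: list[GoldLabel] = []
    for t in range(spec.n_trials):
        trial_id = f"SYN{t:06d}"
        u_kind = rng.random()
        u_field = rng.random()
        ci = int(rng.integers(spec.n_categories))
        syn = cats[ci]
        if u_kind < spec.p_healthy_volunteer:
            trials.append(
                TrialRecord(
                    trial_id,
                    condition="Healthy volunteers",
                    public_title="Recruiting healthy adult volunteers",
                    scientific_title="An observational study of healthy adult volunteers",
                )
            )
            gold.append(GoldLabel(trial_id, frozenset()))
            continue
        threshold = spec.p_healthy_volunteer
        if u_kind < (threshold := threshold + spec.p_multi_label) and spec.n_categories >= 2:
            cj = int((ci + 1 + rng.integers(spec.n_categories - 1)) % spec.n_categories)
            mentioned = [
                syn.trial_terms[int(rng.integers(len(syn.trial_terms)))],
                cats[cj].trial_terms[int(rng.integers(len(cats[cj].trial_terms)))],
            ]
            gold_cats = frozenset({syn.category.id, cats[cj].category.id})
        elif u_kind < (threshold := threshold + spec.p_ambiguous_term) and syn.ambiguous_term:
            mentioned = [
                syn.ambiguous_term,
                syn.trial_terms[int(rng.integers(len(syn.trial_terms)))],
            ]
            gold_cats = frozenset({syn.category.id})
        elif u_kind < threshold + spec.p_enrichment_only and syn.enrichment_term:
            mentioned = [syn.enrichment_term]
            gold_cats = frozenset({syn.category.id})
        else:
            mentioned = [syn.trial_terms[int(rng.integers(len(syn.trial_terms)))]]
            gold_cats = frozenset({syn.category.id})

        phrase = "; ".join(m.title() for m in mentioned)
        in_title = " and ".join(mentioned)
        condition = phrase
        if u_field < spec.p_empty_condition:
            condition = ""
        elif u_field < spec.p_empty_condition + spec.p_title_only:
            condition = "See scientific title"
        trials.append(
            TrialRecord(
                trial_id,
                condition=condition,
                public_title=f"Study of treatment for {in_title}",
                scientific_title=f"A randomized controlled trial of therapy for {in_title} in adults",
            )
        )
        gold.append(GoldLabel(trial_id, gold_cats))

    lexicon = Lexicon(
        concepts=concepts,
        terms=terms,
        parents=parents,
        crosswalk=crosswalk,
        disorder_types=frozenset({_DISORDER_TYPE}),
    )
    enrichment = EnrichmentTable(enrichment_entries)

    save_lexicon(lexicon, lexicon_dir)
    grouping_path = out_dir / "grouping.tsv"
    save_grouping(grouping, grouping_path)
    trials_path = out_dir / "trials.csv"
    write_trials_csv(trials, trials_path)
    gold_path = out_dir / "gold.tsv"
    save_gold(gold, gold_path)
    enrichment_path = out_dir / "enrichment.tsv"
    save_enrichment(enrichment, enrichment_path)

    # reload through the public loaders so the bundle is validated end to end
    grouping = load_grouping(grouping_path, name="synthetic")
    lexicon = load_lexicon(lexicon_dir, disorder_types={_DISORDER_TYPE})
    enrichment = load_enrichment(enrichment_path, grouping)
    return Bundle(
        root=out_dir,
        lexicon_dir=lexicon_dir,
        grouping_path=grouping_path,
        trials_path=trials_path,
        gold_path=gold_path,
        enrichment_path=enrichment_path,
        lexicon=lexicon,
        grouping=grouping,
        enrichment=enrichment,
        trials=trials,
        gold=gold,
    )


def write_trials_csv(trials: Sequence[TrialRecord], path: Union[str, Path]) -> None:
    """Write trials in the registry CSV dialect the readers accept."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(("TrialID", "Public_title", "Scientific_title", "Condition"))
        for t in trials:
            writer.writerow((t.trial_id, t.public_title, t.scientific_title, t.condition))


def _typo(word: str, rng: np.random.Generator) -> str:
    if len(word) < 2:
        return word + "x"
    op = int(rng.integers(3))
    pos = int(rng.integers(len(word) - 1))
    if op == 0:  # swap adjacent characters
        return word[:pos] + word[pos + 1] + word[pos] + word[pos + 2 :]
    if op == 1:  # drop a character
        return word[:pos] + word[pos + 1 :]
    return word[: pos + 1] + word[pos] + word[pos + 1 :]  # double a character


def perturb(
    trials: Sequence[TrialRecord],
    typo_rate: float = 0.0,
    synonym_swap_rate: float = 0.0,
    seed: int = 0,
    lexicon: Optional[Lexicon] = None,
) -> list[TrialRecord]:
    """Seeded text noise: character-level typos and synonym swaps.

    Gold labels are untouched by construction (the trial ids do not
    change).  Synonym swaps need a lexicon to know which surface forms
    name the same concept; without one, only typos are applied.
    """
    if not 0.0 <= typo_rate <= 1.0 or not 0.0 <= synonym_swap_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    synonyms: dict[str, list[str]] = {}
    if lexicon is not None and synonym_swap_rate > 0:
        by_cui: dict[str, list[str]] = {}
        for term, cuis in sorted(lexicon.terms.items()):
            for cui in sorted(cuis):
                by_cui.setdefault(cui, []).append(term)
        for term_list in by_cui.values():
            for term in term_list:
                if len(term_list) > 1:
                    synonyms.setdefault(term, [t for t in term_list if t != term])

    out = []
    for trial in trials:
        fields = {}
        for name in ("condition", "public_title", "scientific_title"):
            text = getattr(trial, name)
            if synonyms:
                for term in sorted(synonyms, key=len, reverse=True):
                    if term in text.lower() and rng.random() < synonym_swap_rate:
                        alts = synonyms[term]
                        repl = alts[int(rng.integers(len(alts)))]
                        idx = text.lower().index(term)
                        text = text[:idx] + repl + text[idx + len(term) :]
            if typo_rate > 0:
                words = text.split(" ")
                words = [
                    _typo(w, rng) if w and rng.random() < typo_rate else w for w in words
                ]
                text = " ".join(words)
            fields[name] = text
        out.append(replace(trial, **fields))
    return out
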
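"""Disorder-concept recognition in trial free text.

A deterministic, exact longest-match dictionary matcher plays the role
an external concept recognizer (such as MetaMap) would play in a
production pipeline: it scans the normalized token stream of a text
field and emits one annotation per matching concept for each maximal
matching span, keeping only concepts with at least one disorder-group
semantic type.  Externally produced annotations can be ingested instead
via :func:`read_annotations`.

Word-sense disambiguation (selecting a single concept when a span
matches several) is a deterministic surrogate: keep the concept whose
preferred name is most similar to the matched text, breaking ties by
smallest concept id.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from difflib import SequenceMatcher
from pathlib import Path
from typing import TYPE_CHECKING, Union

if TYPE_CHECKING:  # pragma: no cover
    from .lexicon import Lexicon

FIELD_NAMES = ("condition", "public_title", "scientific_title")

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


class AnnotationError(ValueError):
    """An externally supplied annotation record is invalid."""


@dataclass(frozen=True)
class Annotation:
    """One concept mention: a character span of a trial field plus its CUI.

    Spans are 0-based half-open; ``matched_text`` is the exact field
    substring at the span.
    """

    field_name: str
    start: int
    end: int
    matched_text: str
    cui: str


def normalize(text: str) -> list[str]:
    """Lowercase, map punctuation to spaces, split into tokens."""
    return [m.group().lower() for m in _TOKEN_RE.finditer(text)]


def normalize_term(text: str) -> str:
    """The canonical single-string form of a term used as dictionary key."""
    return " ".join(normalize(text))


def _tokenize(text: str) -> list[tuple[str, int, int]]:
    return [(m.group().lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def annotate(field_name: str, text: str, lexicon: "Lexicon", wsd: bool = False) -> list[Annotation]:
    """Greedy leftmost-longest dictionary scan of one text field.

    Each maximal matching span yields an annotation for every concept
    whose term equals the span and which has a disorder semantic type;
    with ``wsd=True`` exactly one concept is kept per span.
    """
    if field_name not in FIELD_NAMES:
        raise AnnotationError(f"unknown field name {field_name!r}")
    tokens = _tokenize(text)
    max_len = lexicon.max_term_tokens
    out: list[Annotation] = []
    i = 0
    while i < len(tokens):
        hit = None
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            key = " ".join(tok for tok, _, _ in tokens[i : i + length])
            cuis = sorted(c for c in lexicon.terms.get(key, ()) if lexicon.is_disorder(c))
            if cuis:
                hit = (length, cuis)
                break
        if hit is None:
            i += 1
            continue
        length, cuis = hit
        start, end = tokens[i][1], tokens[i + length - 1][2]
        anns = [Annotation(field_name, start, end, text[start:end], cui) for cui in cuis]
        if wsd and len(anns) > 1:
            anns = [disambiguate(anns, lexicon)]
        out.extend(anns)
        i += length
    return out


def disambiguate(annotations: list[Annotation], lexicon: "Lexicon") -> Annotation:
    """Pick the single concept for a span shared by several annotations.

    The kept concept is the one whose preferred name is most similar to
    the matched text (normalized SequenceMatcher ratio); ties go to the
    lexicographically smallest CUI.
    """
    if not annotations:
        raise AnnotationError("disambiguate requires at least one annotation")
    target = normalize_term(annotations[0].matched_text)

    def rank(ann: Annotation) -> tuple[float, str]:
        name = normalize_term(lexicon.concepts[ann.cui].preferred_name)
        return (-SequenceMatcher(None, name, target).ratio(), ann.cui)

    return min(annotations, key=rank)


def read_annotations(path: Union[str, Path]) -> dict[str, dict[str, list[Annotation]]]:
    """Ingest externally produced annotations from JSON.

    The file holds an array of objects ``{trial_id, field, start, end,
    text, cui}``; the result maps trial id -> field name -> annotations,
    usable in place of the built-in matcher.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise AnnotationError(f"{path}: expected a JSON array of annotation records")
    out: dict[str, dict[str, list[Annotation]]] = {}
    for idx, rec in enumerate(records):
        try:
            trial_id = rec["trial_id"]
            field = rec["field"]
            start = int(rec["start"])
            end = int(rec["end"])
            text = rec["text"]
            cui = rec["cui"]
        except (KeyError, TypeError, ValueError) as exc:
            raise AnnotationError(f"{path}: record {idx}: malformed ({exc})") from exc
        if field not in FIELD_NAMES:
            raise AnnotationError(f"{path}: record {idx}: unknown field name {field!r}")
        if end < start or start < 0:
            raise AnnotationError(f"{path}: record {idx}: invalid span [{start}, {end})")
        out.setdefault(trial_id, {}).setdefault(field, []).append(
            Annotation(field, start, end, text, cui)
        )
    for fields in out.values():
        for anns in fields.values():
            anns.sort(key=lambda a: (a.start, a.end, a.cui))
    return out


def validate_spans(annotations: list[Annotation], text: str) -> None:
    """Check each annotation's span slices its field text to matched_text."""
    for ann in annotations:
        if ann.end > len(text) or text[ann.start : ann.end] != ann.matched_text:
            raise AnnotationError(
                f"annotation span [{ann.start}, {ann.end}) does not match field text "
                f"({ann.matched_text!r})"
            )
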
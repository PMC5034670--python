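"""The mini-metathesaurus bundle: concepts, terms, hierarchy, crosswalk.

The classifier needs four relations from a medical knowledge source:
concept definitions with semantic types, synonym terms naming concepts,
an is-a hierarchy over concepts, and a concept-to-ICD10 crosswalk.  A
full metathesaurus (UMLS) provides all four but is licensed; this module
loads the same structure from an open bundle of TSV files, into which
any licensed subset can be exported.

Files (all UTF-8 TSV with a header row) in one directory:

* ``concepts.tsv``  — cui, preferred_name, semantic_types (semicolon-joined)
* ``terms.tsv``     — cui, term
* ``hierarchy.tsv`` — child_cui, parent_cui
* ``crosswalk.tsv`` — cui, icd10_spec

Only concepts carrying at least one semantic type from the configured
disorder group (diseases or injuries) are eligible for annotation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .annotation import normalize_term
from .taxonomy import GBDGrouping, ICD10ParseError, ICD10Spec, parse_icd10

_CUI_OK = lambda cui: len(cui) > 1 and cui[0] == "C" and cui[1:].isdigit()


class LexiconError(ValueError):
    """A lexicon bundle or enrichment table is invalid."""


def default_disorder_types() -> frozenset[str]:
    """The packaged disorder-group semantic types (UMLS DISO group)."""
    text = resources.files("gbdmap").joinpath("data/disorder_types.txt").read_text("utf-8")
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class Concept:
    cui: str
    preferred_name: str
    semantic_types: frozenset[str]


@dataclass
class Lexicon:
    """Validated in-memory mini-metathesaurus.

    ``terms`` maps normalized term strings to the set of CUIs they name;
    ``parents`` is the (acyclic) is-a relation child -> parents;
    ``crosswalk`` maps CUIs to ICD-10 code/block specs.
    """

    concepts: dict[str, Concept]
    terms: dict[str, set[str]]
    parents: dict[str, set[str]]
    crosswalk: dict[str, tuple[ICD10Spec, ...]]
    disorder_types: frozenset[str]
    max_term_tokens: int = field(init=False)

    def __post_init__(self) -> None:
        self.max_term_tokens = max((len(t.split()) for t in self.terms), default=1)

    def is_disorder(self, cui: str) -> bool:
        return bool(self.concepts[cui].semantic_types & self.disorder_types)

    def disorder_cuis(self) -> set[str]:
        return {c for c in self.concepts if self.is_disorder(c)}


def _read_tsv(path: Path, columns: tuple[str, ...]) -> list[tuple[int, dict[str, str]]]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = reader.fieldnames or []
        missing = [c for c in columns if c not in fields]
        if missing:
            raise LexiconError(f"{path}: missing columns {missing}")
        return [(lineno, row) for lineno, row in enumerate(reader, start=2)]


def _check_acyclic(parents: dict[str, set[str]]) -> None:
    # iterative three-color DFS over the child -> parent relation
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    for root in parents:
        if color.get(root, WHITE) != WHITE:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(root, iter(parents.get(root, ())))]
        color[root] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                state = color.get(nxt, WHITE)
                if state == GREY:
                    raise LexiconError(f"hierarchy cycle involving {nxt!r}")
                if state == WHITE:
                    color[nxt] = GREY
                    stack.append((nxt, iter(parents.get(nxt, ()))))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack.pop()


def load_lexicon(
    directory: Union[str, Path], disorder_types: Optional[Iterable[str]] = None
) -> Lexicon:
    """Load and validate a lexicon bundle from a directory of TSV files.

    Raises :class:`LexiconError` with file and row numbers for duplicate
    CUIs, dangling references, unparsable crosswalk specs or hierarchy
    cycles.
    """
    directory = Path(directory)
    errors: list[str] = []

    concepts: dict[str, Concept] = {}
    for lineno, row in _read_tsv(directory / "concepts.tsv", ("cui", "preferred_name", "semantic_types")):
        cui = (row["cui"] or "").strip()
        if not _CUI_OK(cui):
            errors.append(f"concepts.tsv row {lineno}: invalid cui {cui!r}")
            continue
        if cui in concepts:
            errors.append(f"concepts.tsv row {lineno}: duplicate cui {cui!r}")
            continue
        stypes = frozenset(t.strip() for t in (row["semantic_types"] or "").split(";") if t.strip())
        if not stypes:
            errors.append(f"concepts.tsv row {lineno}: concept {cui!r} has no semantic types")
            continue
        concepts[cui] = Concept(cui, (row["preferred_name"] or "").strip(), stypes)

    terms: dict[str, set[str]] = {}
    for lineno, row in _read_tsv(directory / "terms.tsv", ("cui", "term")):
        cui = (row["cui"] or "").strip()
        if cui not in concepts:
            errors.append(f"terms.tsv row {lineno}: dangling cui {cui!r}")
            continue
        key = normalize_term(row["term"] or "")
        if key:
            terms.setdefault(key, set()).add(cui)

    parents: dict[str, set[str]] = {}
    for lineno, row in _read_tsv(directory / "hierarchy.tsv", ("child_cui", "parent_cui")):
        child = (row["child_cui"] or "").strip()
        parent = (row["parent_cui"] or "").strip()
        bad = [c for c in (child, parent) if c not in concepts]
        if bad:
            errors.append(f"hierarchy.tsv row {lineno}: dangling cui {bad[0]!r}")
            continue
        parents.setdefault(child, set()).add(parent)

    crosswalk: dict[str, list[ICD10Spec]] = {}
    for lineno, row in _read_tsv(directory / "crosswalk.tsv", ("cui", "icd10_spec")):
        cui = (row["cui"] or "").strip()
        if cui not in concepts:
            errors.append(f"crosswalk.tsv row {lineno}: dangling cui {cui!r}")
            continue
        try:
            spec = parse_icd10(row["icd10_spec"] or "")
        except ICD10ParseError as exc:
            errors.append(f"crosswalk.tsv row {lineno}: {exc}")
            continue
        entry = crosswalk.setdefault(cui, [])
        if spec not in entry:
            entry.append(spec)

    if errors:
        raise LexiconError(f"{directory}: " + "; ".join(errors))
    _check_acyclic(parents)

    return Lexicon(
        concepts=concepts,
        terms=terms,
        parents=parents,
        crosswalk={cui: tuple(specs) for cui, specs in crosswalk.items()},
        disorder_types=frozenset(disorder_types) if disorder_types is not None else default_disorder_types(),
    )


def save_lexicon(lexicon: Lexicon, directory: Union[str, Path]) -> None:
    """Write a lexicon bundle back to its four TSV files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    def _write(name: str, header: tuple[str, ...], rows: Iterable[tuple]) -> None:
        with (directory / name).open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    _write(
        "concepts.tsv",
        ("cui", "preferred_name", "semantic_types"),
        (
            (c.cui, c.preferred_name, ";".join(sorted(c.semantic_types)))
            for c in sorted(lexicon.concepts.values(), key=lambda c: c.cui)
        ),
    )
    _write(
        "terms.tsv",
        ("cui", "term"),
        sorted((cui, term) for term, cuis in lexicon.terms.items() for cui in cuis),
    )
    _write(
        "hierarchy.tsv",
        ("child_cui", "parent_cui"),
        sorted((child, parent) for child, ps in lexicon.parents.items() for parent in ps),
    )
    _write(
        "crosswalk.tsv",
        ("cui", "icd10_spec"),
        sorted((cui, str(spec)) for cui, specs in lexicon.crosswalk.items() for spec in specs),
    )


@dataclass
class EnrichmentTable:
    """Expert-curated concept -> GBD category projections.

    Consulted only for concepts with no automatic pathway to any
    category; shipped empty by default and filled by curation.
    """

    entries: dict[str, set[str]]

    def __contains__(self, cui: str) -> bool:
        return cui in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_enrichment(path: Union[str, Path], grouping: GBDGrouping) -> EnrichmentTable:
    """Load an enrichment TSV (cui, category_id), checking ids against the grouping."""
    path = Path(path)
    entries: dict[str, set[str]] = {}
    errors: list[str] = []
    for lineno, row in _read_tsv(path, ("cui", "category_id")):
        cui = (row["cui"] or "").strip()
        cid = (row["category_id"] or "").strip()
        if not _CUI_OK(cui):
            errors.append(f"row {lineno}: invalid cui {cui!r}")
            continue
        if cid not in grouping.categories:
            errors.append(f"row {lineno}: unknown category id {cid!r}")
            continue
        entries.setdefault(cui, set()).add(cid)
    if errors:
        raise LexiconError(f"{path}: " + "; ".join(errors))
    return EnrichmentTable(entries)


def save_enrichment(table: EnrichmentTable, path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("cui", "category_id"))
        writer.writerows(sorted((cui, cid) for cui, cids in table.entries.items() for cid in cids))
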
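"""ICD-10 code arithmetic and Global Burden of Disease (GBD) cause groupings.

The GBD cause list partitions disease and injury space into mutually
exclusive categories, each defined by sets of three- and four-character
ICD-10 codes (``M16``, ``M16.9``) and by blocks of such codes
(``F30-F39.9``).  This module models codes, blocks and groupings, expands
blocks into individual codes, and projects codes onto categories.

Projection follows a unique-inclusion rule: a code is assigned to a GBD
category only if it — together with all of its known four-character
extensions — falls entirely inside a single non-residual category.  A
three-character code whose extensions are claimed by two different
categories (the classic example is ``P37``, whose ``.0`` extension is
tuberculous and whose ``.3`` extension is a neglected tropical disease)
is therefore unprojectable.  Residual catch-all categories may be loaded
for bookkeeping but are never assignable.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import total_ordering
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union


class ICD10ParseError(ValueError):
    """A string is not a valid ICD-10 code or block."""


class GroupingError(ValueError):
    """A grouping definition is structurally invalid."""


_CODE_RE = re.compile(r"^([A-Z])([0-9]{2})(?:\.([0-9]))?$")
# hyphen plus the unicode dash family used by registry exports and journals
_DASH_RE = re.compile("[‐‑‒–—―-]")


@total_ordering
@dataclass(frozen=True)
class ICD10Code:
    """A three- or four-character ICD-10 code.

    ``minor`` is the optional single decimal digit; ``M16`` has
    ``minor=None`` and sorts immediately before ``M16.0``.
    """

    letter: str
    major: int
    minor: Optional[int] = None

    def __post_init__(self) -> None:
        if not (len(self.letter) == 1 and self.letter.isalpha() and self.letter.isupper()):
            raise ICD10ParseError(f"invalid ICD-10 letter {self.letter!r}")
        if not 0 <= self.major <= 99:
            raise ICD10ParseError(f"invalid ICD-10 major part {self.major!r}")
        if self.minor is not None and not 0 <= self.minor <= 9:
            raise ICD10ParseError(f"invalid ICD-10 minor digit {self.minor!r}")

    @property
    def sort_key(self) -> tuple:
        return (self.letter, self.major, -1 if self.minor is None else self.minor)

    def __lt__(self, other: "ICD10Code") -> bool:
        if not isinstance(other, ICD10Code):
            return NotImplemented
        return self.sort_key < other.sort_key

    @property
    def parent(self) -> "ICD10Code":
        """The three-character code this code extends (itself if already 3-char)."""
        return self if self.minor is None else ICD10Code(self.letter, self.major)

    def __str__(self) -> str:
        base = f"{self.letter}{self.major:02d}"
        return base if self.minor is None else f"{base}.{self.minor}"

    def __repr__(self) -> str:
        return f"ICD10Code({str(self)!r})"


@dataclass(frozen=True)
class ICD10Block:
    """An inclusive range of ICD-10 codes, e.g. ``F30-F39.9``.

    A bare three-character end code is an exact endpoint: ``F30-F39``
    ends at ``F39`` itself (extensions ``F39.0``.. sort after it), while
    ``F30-F39.9`` covers every extension of ``F39``.
    """

    start: ICD10Code
    end: ICD10Code

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ICD10ParseError(f"block start {self.start} exceeds end {self.end}")

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"

    def __repr__(self) -> str:
        return f"ICD10Block({str(self)!r})"


ICD10Spec = Union[ICD10Code, ICD10Block]


def _parse_code(token: str) -> ICD10Code:
    m = _CODE_RE.match(token)
    if m is None:
        raise ICD10ParseError(f"not a valid ICD-10 code: {token!r}")
    letter, major, minor = m.groups()
    return ICD10Code(letter, int(major), None if minor is None else int(minor))


def parse_icd10(text: str) -> ICD10Spec:
    """Parse ``"M16.9"`` into a code or ``"F30-F39.9"`` into a block.

    Case is normalized and all common dash dialects (hyphen, en-dash,
    em-dash) are accepted as the block separator.
    """
    cleaned = _DASH_RE.sub("-", text.strip().upper())
    if not cleaned:
        raise ICD10ParseError("empty ICD-10 specification")
    if "-" in cleaned:
        parts = [p.strip() for p in cleaned.split("-")]
        if len(parts) != 2 or not all(parts):
            raise ICD10ParseError(f"not a valid ICD-10 block: {text.strip()!r}")
        return ICD10Block(_parse_code(parts[0]), _parse_code(parts[1]))
    return _parse_code(cleaned)


def expand_block(
    block: ICD10Block, universe: Optional[Iterable[ICD10Code]] = None
) -> list[ICD10Code]:
    """Enumerate, in order, every 3- and 4-character code inside a block.

    The enumeration walks the syntactic grid (each three-character code
    followed by its ten one-decimal extensions) clipped at the block
    endpoints.  If ``universe`` is given the result is intersected with
    it, preserving order.
    """
    allowed = None if universe is None else frozenset(universe)
    out: list[ICD10Code] = []
    for letter_ord in range(ord(block.start.letter), ord(block.end.letter) + 1):
        letter = chr(letter_ord)
        lo = block.start.major if letter == block.start.letter else 0
        hi = block.end.major if letter == block.end.letter else 99
        for major in range(lo, hi + 1):
            for minor in (None, *range(10)):
                code = ICD10Code(letter, major, minor)
                if block.start <= code <= block.end and (allowed is None or code in allowed):
                    out.append(code)
    return out


@dataclass(frozen=True)
class GBDCategory:
    """One cause category of a GBD grouping.

    Residual catch-alls ("Other ...") carry ``residual=True`` and are
    excluded from projection.
    """

    id: str
    name: str
    residual: bool = False


class GBDGrouping:
    """A named partition of ICD-10 space into GBD categories.

    ``assignments`` maps category ids to lists of code/block specs;
    ``code_map`` is the derived map from every expanded code of a
    non-residual category to that category's id.  Construction validates
    mutual exclusivity: no code may be claimed by two distinct
    non-residual categories.
    """

    def __init__(
        self,
        name: str,
        categories: Iterable[GBDCategory],
        assignments: dict[str, list[ICD10Spec]],
    ) -> None:
        self.name = name
        self.categories: dict[str, GBDCategory] = {}
        for cat in categories:
            if cat.id in self.categories:
                raise GroupingError(f"duplicate category id {cat.id!r}")
            self.categories[cat.id] = cat
        if not self.categories:
            raise GroupingError("no categories")
        unknown = sorted(set(assignments) - set(self.categories))
        if unknown:
            raise GroupingError(f"assignments for unknown categories: {unknown}")
        self.assignments = {cid: list(specs) for cid, specs in assignments.items()}
        self.code_map: dict[ICD10Code, str] = {}
        collisions: list[str] = []
        for cid, specs in self.assignments.items():
            if self.categories[cid].residual:
                continue
            for spec in specs:
                codes = [spec] if isinstance(spec, ICD10Code) else expand_block(spec)
                for code in codes:
                    prev = self.code_map.get(code)
                    if prev is not None and prev != cid:
                        collisions.append(f"{code} claimed by {prev!r} and {cid!r}")
                    else:
                        self.code_map[code] = cid
        if collisions:
            raise GroupingError(
                "code collisions between non-residual categories: " + "; ".join(sorted(collisions))
            )
        # universe for block projection: known codes plus 3-char parents of known codes
        self._universe = frozenset(self.code_map) | frozenset(
            c.parent for c in self.code_map if c.minor is not None
        )

    @property
    def non_residual(self) -> list[GBDCategory]:
        return [c for c in self.categories.values() if not c.residual]

    @property
    def residual(self) -> list[GBDCategory]:
        return [c for c in self.categories.values() if c.residual]

    def __repr__(self) -> str:
        return (
            f"GBDGrouping({self.name!r}, {len(self.non_residual)} categories, "
            f"{len(self.residual)} residual)"
        )


def project_code(code: ICD10Code, grouping: GBDGrouping) -> Optional[GBDCategory]:
    """Project a single code onto its GBD category, if unambiguous.

    A four-character code uses its direct entry in the code map, falling
    back to its three-character parent; a three-character code projects
    only when it and every known extension belong to one category.
    Returns ``None`` when no unambiguous category exists — absence is a
    valid outcome, never an error.  Residual categories are never
    returned (they are not in the code map).
    """
    if code.minor is not None:
        cid = grouping.code_map.get(code)
        if cid is not None:
            return grouping.categories[cid]
        return _project_three(code.parent, grouping)
    return _project_three(code, grouping)


def _project_three(code: ICD10Code, grouping: GBDGrouping) -> Optional[GBDCategory]:
    cids = set()
    for candidate in (code, *(ICD10Code(code.letter, code.major, m) for m in range(10))):
        cid = grouping.code_map.get(candidate)
        if cid is not None:
            cids.add(cid)
    if len(cids) == 1:
        return grouping.categories[next(iter(cids))]
    return None


def project_spec(spec: ICD10Spec, grouping: GBDGrouping) -> set[GBDCategory]:
    """Project a code or block onto the set of GBD categories it reaches.

    For a block this is the union of single-code projections over its
    expansion, restricted to codes the grouping knows about (or their
    three-character parents).
    """
    if isinstance(spec, ICD10Code):
        cat = project_code(spec, grouping)
        return set() if cat is None else {cat}
    cats: set[GBDCategory] = set()
    for code in expand_block(spec, universe=grouping._universe):
        cat = project_code(code, grouping)
        if cat is not None:
            cats.add(cat)
    return cats


_GROUPING_COLUMNS = ("category_id", "category_name", "residual_flag", "icd10_spec")
_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


def load_grouping(path: Union[str, Path], name: Optional[str] = None) -> GBDGrouping:
    """Load a grouping from a TSV of (category_id, category_name, residual_flag, icd10_spec).

    A category spans several rows, one ICD-10 spec per row; rows sharing
    a category_id must agree on the name and residual flag.
    """
    path = Path(path)
    categories: dict[str, GBDCategory] = {}
    assignments: dict[str, list[ICD10Spec]] = {}
    errors: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fields = reader.fieldnames or []
        missing = [c for c in _GROUPING_COLUMNS if c not in fields]
        if missing:
            raise GroupingError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            cid = (row["category_id"] or "").strip()
            if not cid:
                errors.append(f"row {lineno}: empty category_id")
                continue
            flag_text = (row["residual_flag"] or "").strip().lower()
            if flag_text in _TRUE:
                residual = True
            elif flag_text in _FALSE:
                residual = False
            else:
                errors.append(f"row {lineno}: bad residual_flag {row['residual_flag']!r}")
                continue
            cat = GBDCategory(cid, (row["category_name"] or "").strip(), residual)
            prev = categories.get(cid)
            if prev is None:
                categories[cid] = cat
            elif prev != cat:
                errors.append(f"row {lineno}: duplicate category id {cid!r} with conflicting definition")
                continue
            spec_text = (row["icd10_spec"] or "").strip()
            if spec_text:
                try:
                    assignments.setdefault(cid, []).append(parse_icd10(spec_text))
                except ICD10ParseError as exc:
                    errors.append(f"row {lineno}: {exc}")
    if errors:
        raise GroupingError(f"{path}: " + "; ".join(errors))
    if not categories:
        raise GroupingError(f"{path}: no categories")
    return GBDGrouping(name or path.stem, categories.values(), assignments)


def packaged_grouping() -> GBDGrouping:
    """The shipped 28-class GBD 2010 grouping (plus 2 residual categories).

    The category list follows the published 28-class consensus grouping;
    the ICD-10 assignments are this package's curation of standard
    chapter ranges (the original cause-by-cause crosswalk is licensed
    and not redistributable) — see docs/methods.md.
    """
    with resources.as_file(resources.files("gbdmap").joinpath("data/gbd28.tsv")) as p:
        return load_grouping(p, name="gbd28")


def save_grouping(grouping: GBDGrouping, path: Union[str, Path]) -> None:
    """Write a grouping back to the TSV format read by :func:`load_grouping`."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_GROUPING_COLUMNS)
        for cid, cat in grouping.categories.items():
            specs = grouping.assignments.get(cid, [])
            for spec in specs:
                writer.writerow([cat.id, cat.name, int(cat.residual), str(spec)])
            if not specs:
                writer.writerow([cat.id, cat.name, int(cat.residual), ""])
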
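"""Readers for trial-registry export formats and writers for outputs.

Two registry dialects are supported: the WHO ICTRP export (``Trial``
elements with ``TrialID`` / ``Public_title`` / ``Scientific_title`` /
``Condition`` children, or a CSV with the same headers) and
clinicaltrials.gov study XML (``brief_title`` / ``official_title`` /
``condition``).  Field-name mappings are data, not code, so new export
dialects can be absorbed by editing the tables below.

Readers reject nothing silently: records that cannot be read raise (or,
in lenient contexts, are logged with a reason by the caller).
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from lxml import etree

from .classifier import Classification, TrialRecord
from .evaluation import NO_GBD, EvalReport, ExactMatchingResult

logger = logging.getLogger(__name__)


class RegistryReadError(ValueError):
    """A registry export could not be read."""


# element-tag -> TrialRecord field mappings (data, not code)
ICTRP_XML_FIELDS = {
    "TrialID": "trial_id",
    "Public_title": "public_title",
    "Scientific_title": "scientific_title",
    "Condition": "condition",
}
CTGOV_XML_FIELDS = {
    "brief_title": "public_title",
    "official_title": "scientific_title",
    "condition": "condition",
}
CSV_FIELDS = {
    "trialid": "trial_id",
    "public_title": "public_title",
    "scientific_title": "scientific_title",
    "condition": "condition",
}


def _clean(text: Optional[str]) -> str:
    if text is None:
        return ""
    # multi-entry fields separated by line breaks keep a separator for annotation
    return "; ".join(part.strip() for part in text.splitlines() if part.strip())


def read_ictrp(path: Union[str, Path]) -> list[TrialRecord]:
    """Read an ICTRP export, either XML (``Trial`` elements) or CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_csv(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise RegistryReadError(f"{path}: {exc}") from exc
    records = []
    trials = tree.findall(".//Trial")
    for idx, trial in enumerate(trials):
        fields = {"condition": "", "public_title": "", "scientific_title": ""}
        trial_id = None
        for tag, attr in ICTRP_XML_FIELDS.items():
            values = [_clean(el.text) for el in trial.findall(tag)]
            joined = "; ".join(v for v in values if v)
            if attr == "trial_id":
                trial_id = joined or None
            else:
                fields[attr] = joined
        if not trial_id:
            raise RegistryReadError(f"{path}: Trial element {idx} lacks TrialID")
        records.append(TrialRecord(trial_id, **fields))
    return records


def _read_csv(path: Path) -> list[TrialRecord]:
    records = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if not reader.fieldnames:
            raise RegistryReadError(f"{path}: empty CSV")
        colmap = {}
        for col in reader.fieldnames:
            attr = CSV_FIELDS.get(col.strip().lower())
            if attr:
                colmap[col] = attr
        if "trial_id" not in colmap.values():
            raise RegistryReadError(f"{path}: no TrialID column")
        for lineno, row in enumerate(reader, start=2):
            fields = {"condition": "", "public_title": "", "scientific_title": ""}
            trial_id = None
            for col, attr in colmap.items():
                value = _clean(row.get(col))
                if attr == "trial_id":
                    trial_id = value or None
                else:
                    fields[attr] = value
            if not trial_id:
                raise RegistryReadError(f"{path}: row {lineno} lacks TrialID")
            records.append(TrialRecord(trial_id, **fields))
    return records


def read_ctgov(path: Union[str, Path]) -> list[TrialRecord]:
    """Read clinicaltrials.gov study XML (one study or a batch of studies)."""
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise RegistryReadError(f"{path}: {exc}") from exc
    root = tree.getroot()
    studies = [root] if root.tag == "clinical_study" else root.findall(".//clinical_study")
    if not studies:
        raise RegistryReadError(f"{path}: no clinical_study elements")
    records = []
    for idx, study in enumerate(studies):
        nct = study.findtext("id_info/nct_id")
        if not nct or not nct.strip():
            raise RegistryReadError(f"{path}: study {idx} lacks id_info/nct_id")
        fields = {"condition": "", "public_title": "", "scientific_title": ""}
        for tag, attr in CTGOV_XML_FIELDS.items():
            values = [_clean(el.text) for el in study.findall(tag)]
            fields[attr] = "; ".join(v for v in values if v)
        records.append(TrialRecord(nct.strip(), **fields))
    return records


def read_trials(path: Union[str, Path], fmt: str = "ictrp") -> list[TrialRecord]:
    """Dispatch on export format: ``ictrp`` (XML or CSV), ``ctgov`` or ``csv``."""
    if fmt in ("ictrp", "csv"):
        return read_ictrp(path)
    if fmt == "ctgov":
        return read_ctgov(path)
    raise ValueError(f"unknown format {fmt!r}")


# --- output writers ----------------------------------------------------------


def write_classifications(results: Iterable[Classification], path: Union[str, Path]) -> None:
    """TSV: trial_id, categories (semicolon-joined ids), no_gbd (0/1)."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("trial_id", "categories", "no_gbd"))
        for r in results:
            writer.writerow((r.trial_id, ";".join(sorted(r.categories)), int(r.no_gbd)))


def read_classifications(path: Union[str, Path]) -> list[Classification]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if not reader.fieldnames or "trial_id" not in reader.fieldnames:
            raise RegistryReadError(f"{path}: not a classification TSV")
        for row in reader:
            cats = frozenset(c for c in (row.get("categories") or "").split(";") if c)
            out.append(Classification(row["trial_id"], cats))
    return out


def _fmt_pct(value: Optional[float]) -> str:
    return "-" if value is None else f"{100 * value:.1f}"


def _fmt_ratio(value: Optional[float]) -> str:
    return "-" if value is None else f"{value:.3g}"


def _fmt_ci(ci: Optional[tuple[float, float]], pct: bool = True) -> str:
    if ci is None:
        return "-"
    lo, hi = ci
    if pct:
        return f"[{100 * lo:.1f}-{100 * hi:.1f}]"
    return f"[{lo:.3g}-{hi:.3g}]"


def _exact_dict(r: ExactMatchingResult) -> dict:
    def one(s):
        return {"hits": s.hits, "n": s.n, "proportion": s.proportion}

    return {
        "overall": one(r.overall),
        "one_category": one(r.one_category),
        "two_or_more": one(r.two_or_more),
        "no_category": one(r.no_category),
    }


def write_report(report: EvalReport, prefix: Union[str, Path]) -> tuple[Path, Path]:
    """Emit an evaluation report as ``<prefix>.tsv`` (per-category rows
    mirroring the diagnostic-accuracy table layout) and ``<prefix>.json``
    (exact-matching strata and weighted averages)."""
    prefix = Path(prefix)
    tsv_path = prefix.with_suffix(prefix.suffix + ".tsv")
    json_path = prefix.with_suffix(prefix.suffix + ".json")
    with tsv_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            (
                "category_id", "n_gold", "tp", "fp", "tn", "fn",
                "sen_pct", "sen_ci", "spe_pct", "spe_ci", "ppv_pct", "ppv_ci",
                "lr_plus", "lr_plus_ci", "lr_minus", "lr_minus_ci",
            )
        )
        for m in report.per_category:
            writer.writerow(
                (
                    m.category_id, m.gold_positives, m.tp, m.fp, m.tn, m.fn,
                    _fmt_pct(m.sensitivity), _fmt_ci(m.sensitivity_ci),
                    _fmt_pct(m.specificity), _fmt_ci(m.specificity_ci),
                    _fmt_pct(m.ppv), _fmt_ci(m.ppv_ci),
                    _fmt_ratio(m.lr_plus), _fmt_ci(m.lr_plus_ci, pct=False),
                    _fmt_ratio(m.lr_minus), _fmt_ci(m.lr_minus_ci, pct=False),
                )
            )
    payload = {
        "exact_matching": _exact_dict(report.exact),
        "weighted_sensitivity": report.weighted_sensitivity,
        "weighted_specificity": report.weighted_specificity,
    }
    if report.by_source is not None:
        payload["by_source"] = {k: _exact_dict(v) for k, v in report.by_source.items()}
    json_path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    return tsv_path, json_path
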
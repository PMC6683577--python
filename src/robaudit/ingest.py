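"""Reading RoB tables and applying the exclusion rules.

Two source formats are supported, both offline:

* the flat **interchange** format (CSV or JSONL) with columns
  ``review_id, study_id, domain, judgment, support[, study_design]``;
* a documented **HTML fixture dialect** emulating the structure of a
  review's "Characteristics of included studies" page (per-study section:
  identifier heading, characteristics table, then a "Risk of bias" table
  with columns Bias / Authors' judgement / Support for judgement).

Interchange convention: a row whose ``domain`` field is empty marks a study
that appears in the review but has no RoB table at all, so that pathology is
representable in the flat format as well as in HTML.

Judgments are normalised case-insensitively from low/unclear/high with
optional " risk" / " risk of bias" suffixes; anything else (for example
"moderate") is a customised judgment, kept verbatim and excluded downstream.

``apply_exclusions`` applies the study-level exclusion rules in a fixed
order, so every excluded study carries exactly one primary reason:

1. ROB_TABLE_MISSING / DUPLICATE_ENTRY (from reader warnings or duplicate rows)
2. DOMAIN_MISSING (no row matches the sequence-generation domain matcher)
3. CUSTOMISED_JUDGMENT (judgment not one of the three standard values)
4. EMPTY_SUPPORT (support empty or an "N/A" placeholder)
"""

from __future__ import annotations

import csv
import io
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import html as lxml_html

from .taxonomy import Judgment

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ParseError",
    "RoBEntry",
    "IngestWarning",
    "ExclusionRecord",
    "Corpus",
    "EXCLUSION_REASONS",
    "normalize_judgment",
    "is_sequence_generation_domain",
    "read_interchange",
    "write_interchange",
    "parse_rob_fixture_html",
    "apply_exclusions",
    "write_exclusion_report",
]

SEQUENCE_GENERATION_DOMAIN = "Random sequence generation (selection bias)"

EXCLUSION_REASONS = (
    "CUSTOMISED_JUDGMENT",
    "DOMAIN_MISSING",
    "ROB_TABLE_MISSING",
    "EMPTY_SUPPORT",
    "DUPLICATE_ENTRY",
    "NON_RANDOMISED",
    "ABSTRACT_ONLY",
    "UNEXPLAINED",
)

# Closed set of support placeholders meaning "not available".
_NA_PLACEHOLDERS = frozenset({"n/a", "na", "not applicable"})

_JUDGMENT_RE = re.compile(
    r"^\s*(low|unclear|high)(\s+risk(\s+of\s+bias)?)?\s*$", re.IGNORECASE
)


class FormatError(ValueError):
    """Malformed interchange input (missing column, undecodable bytes...)."""


class ParseError(ValueError):
    """HTML fixture markup in which no study section can be located."""


def normalize_judgment(text: str) -> Judgment | None:
    """Map a raw judgment string to a standard value, or None if customised.

    Accepts "low"/"unclear"/"high" case-insensitively with optional
    " risk" or " risk of bias" suffixes.
    """
    m = _JUDGMENT_RE.match(text or "")
    if m is None:
        return None
    return Judgment(m.group(1).upper())


def is_sequence_generation_domain(domain_name: str) -> bool:
    """Match the random-sequence-generation domain among variably labelled rows."""
    d = (domain_name or "").lower()
    if "random sequence generation" in d:
        return True
    return "sequence generation" in d and "allocation" not in d


@dataclass(frozen=True)
class RoBEntry:
    """One trial x domain row of a RoB table."""

    review_id: str
    study_id: str
    domain_name: str
    judgment_raw: str
    judgment: Judgment | None
    support_text: str
    study_design: str | None = None  # RCT | NRS | UNCLEAR

    @property
    def is_sequence_generation(self) -> bool:
        return is_sequence_generation_domain(self.domain_name)

    @classmethod
    def from_fields(
        cls,
        review_id: str,
        study_id: str,
        domain: str,
        judgment: str,
        support: str,
        study_design: str | None = None,
    ) -> "RoBEntry":
        return cls(
            review_id=review_id,
            study_id=study_id,
            domain_name=domain,
            judgment_raw=judgment,
            judgment=normalize_judgment(judgment),
            support_text=support,
            study_design=study_design or None,
        )


@dataclass(frozen=True)
class IngestWarning:
    """Reader-level anomaly consumed by ``apply_exclusions``."""

    kind: str  # ROB_TABLE_MISSING | DUPLICATE_ENTRY | STUDY_COUNT_MISMATCH
    review_id: str
    study_id: str
    detail: str = ""


@dataclass(frozen=True)
class ExclusionRecord:
    review_id: str
    study_id: str
    reason: str
    detail: str = ""
    study_design: str | None = None


@dataclass
class Corpus:
    """Exclusion-filtered collection of sequence-generation entries."""

    included: list[RoBEntry]
    passthrough: list[RoBEntry] = field(default_factory=list)
    exclusions: list[ExclusionRecord] = field(default_factory=list)
    warnings: list[IngestWarning] = field(default_factory=list)
    review_ids_seen: list[str] = field(default_factory=list)

    @property
    def n_included(self) -> int:
        return len(self.included)

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    @property
    def n_studies_seen(self) -> int:
        return self.n_included + self.n_excluded

    @property
    def included_review_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.included:
            seen.setdefault(e.review_id, None)
        return list(seen)

    @property
    def n_reviews_seen(self) -> int:
        return len(self.review_ids_seen)

    @property
    def n_reviews_included(self) -> int:
        return len(self.included_review_ids)

    @property
    def n_reviews_excluded(self) -> int:
        """Reviews that lost every study to exclusion."""
        return self.n_reviews_seen - self.n_reviews_included

    def exclusion_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.exclusions:
            counts[rec.reason] = counts.get(rec.reason, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# interchange readers / writers

_MANDATORY_COLUMNS = ("review_id", "study_id", "domain", "judgment", "support")


def _open_text(source) -> io.TextIOBase:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline="")
    return source


def read_interchange(source, dialect: str = "csv") -> list[RoBEntry]:
    """Read RoB entries from the interchange format.

    Parameters
    ----------
    source:
        Path or open text stream (UTF-8).
    dialect:
        "csv" (RFC-4180, header required) or "jsonl" (one object per line).
    """
    if dialect not in ("csv", "jsonl"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    close = isinstance(source, (str, Path))
    stream = _open_text(source)
    try:
        try:
            if dialect == "csv":
                return _read_csv(stream)
            return _read_jsonl(stream)
        except UnicodeDecodeError as exc:
            raise FormatError(
                f"input is not valid UTF-8 at byte offset {exc.start}"
            ) from exc
    finally:
        if close:
            stream.close()


def _entry_from_record(rec: Mapping[str, str], where: str) -> RoBEntry:
    missing = [c for c in _MANDATORY_COLUMNS if c not in rec or rec[c] is None]
    if missing:
        raise FormatError(f"{where}: missing mandatory column(s): {', '.join(missing)}")
    return RoBEntry.from_fields(
        review_id=str(rec["review_id"]),
        study_id=str(rec["study_id"]),
        domain=str(rec["domain"]),
        judgment=str(rec["judgment"]),
        support=str(rec["support"]),
        study_design=(str(rec["study_design"]) if rec.get("study_design") else None),
    )


def _read_csv(stream) -> list[RoBEntry]:
    reader = csv.DictReader(stream)
    if reader.fieldnames is None:
        return []
    missing = [c for c in _MANDATORY_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    return [_entry_from_record(row, f"row {i}") for i, row in enumerate(reader, start=2)]


def _read_jsonl(stream) -> list[RoBEntry]:
    entries = []
    for i, line in enumerate(stream, start=1):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"line {i}: invalid JSON: {exc}") from exc
        entries.append(_entry_from_record(rec, f"line {i}"))
    return entries


def write_interchange(entries: Iterable[RoBEntry], target, dialect: str = "csv") -> None:
    """Write entries in the interchange format (inverse of ``read_interchange``)."""
    close = isinstance(target, (str, Path))
    stream = (
        open(target, "w", encoding="utf-8", newline="") if close else target
    )
    try:
        if dialect == "csv":
            writer = csv.writer(stream, lineterminator="\n")
            writer.writerow(list(_MANDATORY_COLUMNS) + ["study_design"])
            for e in entries:
                writer.writerow([
                    e.review_id, e.study_id, e.domain_name,
                    e.judgment_raw, e.support_text, e.study_design or "",
                ])
        elif dialect == "jsonl":
            for e in entries:
                rec = {
                    "review_id": e.review_id,
                    "study_id": e.study_id,
                    "domain": e.domain_name,
                    "judgment": e.judgment_raw,
                    "support": e.support_text,
                }
                if e.study_design:
                    rec["study_design"] = e.study_design
                stream.write(json.dumps(rec) + "\n")
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# HTML fixture dialect

def parse_rob_fixture_html(source) -> tuple[list[RoBEntry], list[IngestWarning]]:
    """Parse the HTML fixture dialect.

    The dialect mirrors the page structure of a review's "Characteristics of
    included studies" section: ``div.review`` blocks (review id in the ``id``
    attribute) containing ``div.study`` blocks — a study identifier heading, a
    characteristics table, then an ``h3`` titled "Risk of bias" followed by a
    table with columns Bias / Authors' judgement / Support for judgement.

    Returns entries plus warnings for studies lacking a RoB table and for
    duplicated study sections; both are consumed by ``apply_exclusions``.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists():
        text = Path(source).read_text(encoding="utf-8")
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)

    try:
        doc = lxml_html.fromstring(text)
    except Exception as exc:  # lxml raises several parser error types
        raise ParseError(f"cannot parse HTML document: {exc}") from exc

    reviews = doc.xpath("//div[contains(concat(' ', normalize-space(@class), ' '), ' review ')]")
    if not reviews:
        raise ParseError("no review section (div.review) found in document")

    entries: list[RoBEntry] = []
    warnings: list[IngestWarning] = []

    for rev in reviews:
        review_id = rev.get("id") or rev.get("data-review-id") or ""
        studies = rev.xpath(".//div[contains(concat(' ', normalize-space(@class), ' '), ' study ')]")
        if not studies:
            raise ParseError(f"review {review_id!r}: no study section (div.study) found")
        seen_ids: set[str] = set()
        for study in studies:
            headings = study.xpath(".//h2")
            study_id = (
                headings[0].text_content().strip() if headings else (study.get("id") or "")
            )
            if not study_id:
                raise ParseError(f"review {review_id!r}: study section without identifier heading")
            if study_id in seen_ids:
                warnings.append(IngestWarning(
                    kind="DUPLICATE_ENTRY",
                    review_id=review_id,
                    study_id=study_id,
                    detail="duplicated study section",
                ))
                continue
            seen_ids.add(study_id)
            design = study.get("data-study-design")

            rob_tables = study.xpath(
                ".//h3[normalize-space(text())='Risk of bias']/following-sibling::table[1]"
            )
            if not rob_tables:
                warnings.append(IngestWarning(
                    kind="ROB_TABLE_MISSING",
                    review_id=review_id,
                    study_id=study_id,
                    detail="no 'Risk of bias' table in study section",
                ))
                continue
            for tr in rob_tables[0].xpath(".//tr[td]"):
                cells = [td.text_content().strip() for td in tr.xpath("./td")]
                if len(cells) < 3:
                    continue
                entries.append(RoBEntry.from_fields(
                    review_id=review_id,
                    study_id=study_id,
                    domain=cells[0],
                    judgment=cells[1],
                    support=cells[2],
                    study_design=design,
                ))
    return entries, warnings


# ---------------------------------------------------------------------------
# exclusion rules

def _normalize_support(text: str) -> str:
    return re.sub(r"\s+", " ", (text or "").strip().strip(".").lower())


def apply_exclusions(
    entries: Sequence[RoBEntry],
    warnings: Sequence[IngestWarning] = (),
    declared_study_counts: Mapping[str, int] | None = None,
    extra_na_placeholders: Iterable[str] = (),
) -> Corpus:
    """Apply the study-level exclusion rules in fixed order; build a Corpus.

    Each excluded study receives exactly one primary reason (the first rule
    that fires).  Sequence-generation rows of surviving studies enter
    ``Corpus.included``; rows for other RoB domains pass through untouched.
    If ``declared_study_counts`` is given, a per-review mismatch between the
    declared number of included studies and the number of RoB tables observed
    is logged as a warning, never silently dropped.
    """
    na_set = _NA_PLACEHOLDERS | {_normalize_support(p) for p in extra_na_placeholders}

    # group rows by study, preserving first-appearance order
    by_study: dict[tuple[str, str], list[RoBEntry]] = {}
    review_order: dict[str, None] = {}
    for e in entries:
        by_study.setdefault((e.review_id, e.study_id), []).append(e)
        review_order.setdefault(e.review_id, None)

    warn_by_study: dict[tuple[str, str], IngestWarning] = {}
    for w in warnings:
        if w.kind in ("ROB_TABLE_MISSING", "DUPLICATE_ENTRY"):
            warn_by_study.setdefault((w.review_id, w.study_id), w)
            review_order.setdefault(w.review_id, None)

    corpus = Corpus(included=[], review_ids_seen=list(review_order))
    corpus.warnings.extend(warnings)

    handled_warned = set()

    for key, rows in by_study.items():
        review_id, study_id = key
        design = next((r.study_design for r in rows if r.study_design), None)

        def exclude(reason: str, detail: str) -> None:
            corpus.exclusions.append(ExclusionRecord(
                review_id=review_id, study_id=study_id,
                reason=reason, detail=detail, study_design=design,
            ))

        # rule 1: reader warnings and duplicate rows
        w = warn_by_study.get(key)
        if w is not None:
            handled_warned.add(key)
            exclude(w.kind, w.detail)
            continue
        domains = [r.domain_name for r in rows]
        if len(domains) != len(set(domains)):
            exclude("DUPLICATE_ENTRY", "duplicated domain row(s) within study")
            continue
        if all(not r.domain_name.strip() for r in rows):
            exclude("ROB_TABLE_MISSING", "no RoB table for study (placeholder row)")
            continue

        # rule 2: sequence-generation domain missing
        seq_rows = [r for r in rows if r.is_sequence_generation]
        others = [r for r in rows if not r.is_sequence_generation and r.domain_name.strip()]
        if not seq_rows:
            exclude("DOMAIN_MISSING", "no random-sequence-generation domain row")
            continue
        seq = seq_rows[0]

        # rule 3: customised (non-standard) judgment
        if seq.judgment is None:
            detail = (
                f"customised judgment: {seq.judgment_raw!r}"
                if seq.judgment_raw.strip() else "judgment missing"
            )
            exclude("CUSTOMISED_JUDGMENT", detail)
            continue

        # rule 4: empty or N/A support
        if _normalize_support(seq.support_text) in na_set or not seq.support_text.strip():
            exclude("EMPTY_SUPPORT", f"support field: {seq.support_text!r}")
            continue

        corpus.included.append(seq)
        corpus.passthrough.extend(others)

    # warning-only studies with no rows at all (e.g. HTML study w/o RoB table)
    for key, w in warn_by_study.items():
        if key in by_study or key in handled_warned:
            continue
        corpus.exclusions.append(ExclusionRecord(
            review_id=w.review_id, study_id=w.study_id,
            reason=w.kind, detail=w.detail,
        ))

    if declared_study_counts:
        observed: dict[str, int] = {}
        for (rid, _sid) in by_study:
            observed[rid] = observed.get(rid, 0) + 1
        for (rid, _sid) in warn_by_study:
            if (rid, _sid) not in by_study:
                observed[rid] = observed.get(rid, 0) + 1
        for rid, declared in declared_study_counts.items():
            got = observed.get(rid, 0)
            if got != declared:
                msg = f"review {rid}: declared {declared} studies, observed {got} RoB tables"
                logger.warning(msg)
                corpus.warnings.append(IngestWarning(
                    kind="STUDY_COUNT_MISMATCH", review_id=rid, study_id="", detail=msg,
                ))

    for rec in corpus.exclusions:
        logger.info(
            "excluded %s/%s: %s (%s)", rec.review_id, rec.study_id, rec.reason, rec.detail
        )
    return corpus


def write_exclusion_report(corpus: Corpus, target) -> None:
    """Write the exclusion accounting as CSV: review_id,study_id,reason,detail."""
    close = isinstance(target, (str, Path))
    stream = open(target, "w", encoding="utf-8", newline="") if close else target
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow(["review_id", "study_id", "reason", "detail", "study_design"])
        for rec in corpus.exclusions:
            writer.writerow(
                [rec.review_id, rec.study_id, rec.reason, rec.detail, rec.study_design or ""]
            )
    finally:
        if close:
            stream.close()
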
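"""End-to-end audit pipeline: ingest -> exclusions -> classify -> assess -> summarise.

Thin orchestration over the stage modules so the whole audit is one library
call; the CLI wraps this and nothing else.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .classifier import ClassifiedTrial, RuleSet, classify_corpus, default_ruleset
from .concordance import (
    ConcordanceSummary,
    CrossTab,
    assess,
    build_crosstab,
    render_table,
    summarize,
)
from .ingest import (
    Corpus,
    IngestWarning,
    RoBEntry,
    apply_exclusions,
    parse_rob_fixture_html,
    read_interchange,
    write_exclusion_report,
)
from .taxonomy import Taxonomy, build_taxonomy

__all__ = ["AuditResult", "read_any", "run_audit", "write_classified_csv"]


@dataclass
class AuditResult:
    """Everything one audit run produces, stage by stage."""

    corpus: Corpus
    trials: list[ClassifiedTrial]
    crosstab: CrossTab
    summary: ConcordanceSummary
    taxonomy: Taxonomy

    def render_table(self) -> str:
        return render_table(self.crosstab, self.taxonomy)


def read_any(source, dialect: str = "csv") -> tuple[list[RoBEntry], list[IngestWarning]]:
    """Read entries from any supported dialect (csv, jsonl, html)."""
    if dialect == "html":
        return parse_rob_fixture_html(source)
    return read_interchange(source, dialect=dialect), []


def run_audit(
    entries: Sequence[RoBEntry],
    warnings: Sequence[IngestWarning] = (),
    rules: RuleSet | None = None,
    strict_handbook: bool = False,
) -> AuditResult:
    """Run the full audit on already-read entries."""
    rules = rules or default_ruleset()
    taxonomy = build_taxonomy(strict_handbook=strict_handbook)
    corpus = apply_exclusions(entries, warnings)
    trials = assess(classify_corpus(corpus, rules, taxonomy), taxonomy)
    crosstab = build_crosstab(trials)
    summary = summarize(crosstab, taxonomy)
    return AuditResult(
        corpus=corpus, trials=trials, crosstab=crosstab,
        summary=summary, taxonomy=taxonomy,
    )


def write_classified_csv(trials: Sequence[ClassifiedTrial], target) -> None:
    """Interchange columns plus category, parent, expected judgment, pattern."""
    close = isinstance(target, (str, Path))
    stream = open(target, "w", encoding="utf-8", newline="") if close else target
    try:
        writer = csv.writer(stream, lineterminator="\n")
        writer.writerow([
            "review_id", "study_id", "domain", "judgment", "support",
            "category", "parent", "expected_judgment", "concordant",
            "matched_pattern",
        ])
        for t in trials:
            writer.writerow([
                t.entry.review_id, t.entry.study_id, t.entry.domain_name,
                t.entry.judgment_raw, t.entry.support_text,
                t.category.value, t.parent.value, t.expected.value,
                "" if t.concordant is None else str(t.concordant).lower(),
                t.matched_pattern,
            ])
    finally:
        if close:
            stream.close()
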
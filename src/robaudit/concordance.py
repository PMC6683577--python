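"""Concordance between authors' judgments and Handbook-expected judgments.

A judgment is *concordant* (adequate) when it equals the expected judgment
of the parent category of its support comment; otherwise it is discordant
(inadequate).  This module sets the concordance flag, builds the category x
judgment cross-tabulation, and derives every summary the audit reports:
overall discordance, discordance within each observed judgment, per-category
and per-parent adequacy, and row shares.

Percentages are reported in two roundings — one decimal (table style) and
nearest integer (prose style) — because audit reports conventionally mix
both.  Percentages of empty groups are None (undefined), never 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .classifier import ClassifiedTrial
from .taxonomy import (
    CategoryId,
    Judgment,
    ParentCategory,
    Taxonomy,
    build_taxonomy,
)

__all__ = [
    "ClassifiedTrial",  # produced by the classifier, assessed here
    "GroupStat",
    "CrossTab",
    "ConcordanceSummary",
    "assess",
    "build_crosstab",
    "summarize",
    "summarize_from_counts",
    "render_table",
]

# Column order used in every output: Total, High, Unclear, Low.
JUDGMENT_ORDER = (Judgment.HIGH, Judgment.UNCLEAR, Judgment.LOW)


class IntegrityError(ValueError):
    """A cross-tabulation violating its conservation invariants."""


@dataclass(frozen=True)
class GroupStat:
    """Total and discordant count for one group, with both percent styles."""

    total: int
    discordant: int

    @property
    def concordant(self) -> int:
        return self.total - self.discordant

    @property
    def percent(self) -> float | None:
        """Exact discordant percentage, or None for an empty group."""
        if self.total == 0:
            return None
        return 100.0 * self.discordant / self.total

    @property
    def percent_1dp(self) -> float | None:
        p = self.percent
        return None if p is None else round(p, 1)

    @property
    def percent_int(self) -> int | None:
        p = self.percent
        return None if p is None else round(p)

    @property
    def concordant_percent_1dp(self) -> float | None:
        if self.total == 0:
            return None
        return round(100.0 * self.concordant / self.total, 1)

    @property
    def concordant_percent_int(self) -> int | None:
        if self.total == 0:
            return None
        return round(100.0 * self.concordant / self.total)


def assess(
    trials: Iterable[ClassifiedTrial], taxonomy: Taxonomy | None = None
) -> list[ClassifiedTrial]:
    """Set the concordance flag on every classified trial.

    Pure function of its inputs: concordant iff observed == expected.  If a
    taxonomy is given, parent and expected judgment are recomputed under it
    (this is how the strict-Handbook sensitivity re-assesses a corpus).
    """
    out = []
    for t in trials:
        if taxonomy is not None:
            parent = taxonomy.parent_of(t.category)
            expected = taxonomy.expected_of(parent)
        else:
            parent, expected = t.parent, t.expected
        out.append(ClassifiedTrial(
            entry=t.entry,
            category=t.category,
            parent=parent,
            expected=expected,
            observed=t.observed,
            concordant=(t.observed == expected),
            matched_tier=t.matched_tier,
            matched_pattern=t.matched_pattern,
            trace=t.trace,
        ))
    return out


@dataclass(frozen=True)
class CrossTab:
    """Category x judgment counts with parent-level aggregation."""

    cells: Mapping[tuple[CategoryId, Judgment], int]

    def __post_init__(self):
        for (c, j), v in self.cells.items():
            CategoryId(c), Judgment(j)
            if v < 0:
                raise ValueError(f"negative cell count for ({c}, {j}): {v}")

    @classmethod
    def from_counts(cls, cells: Mapping[tuple[CategoryId, Judgment], int]) -> "CrossTab":
        """Build from an explicit full 19 x 3 mapping (e.g. a published table)."""
        full = {}
        for c in CategoryId:
            for j in Judgment:
                key = (c, j)
                if key not in cells:
                    raise ValueError(f"missing cell ({c.value}, {j.value})")
                full[key] = int(cells[key])
        return cls(cells=full)

    @property
    def n(self) -> int:
        return sum(self.cells.values())

    def cell(self, category: CategoryId, judgment: Judgment) -> int:
        return int(self.cells.get((CategoryId(category), Judgment(judgment)), 0))

    def category_total(self, category: CategoryId) -> int:
        return sum(self.cell(category, j) for j in Judgment)

    def judgment_total(self, judgment: Judgment) -> int:
        return sum(self.cell(c, judgment) for c in CategoryId)

    def parent_cell(
        self, parent: ParentCategory, judgment: Judgment, taxonomy: Taxonomy
    ) -> int:
        return sum(self.cell(c, judgment) for c in taxonomy.members_of(parent))

    def parent_total(self, parent: ParentCategory, taxonomy: Taxonomy) -> int:
        return sum(self.category_total(c) for c in taxonomy.members_of(parent))

    def row_percent(self, category: CategoryId, judgment: Judgment) -> float | None:
        """Share of a category's trials given one judgment, in % (1 decimal)."""
        total = self.category_total(category)
        if total == 0:
            return None
        return round(100.0 * self.cell(category, judgment) / total, 1)

    def validate(self, taxonomy: Taxonomy | None = None) -> None:
        """Check conservation: parents sum to members, columns sum to n."""
        taxonomy = taxonomy or build_taxonomy()
        n = self.n
        if sum(self.judgment_total(j) for j in Judgment) != n:
            raise IntegrityError("judgment totals do not sum to n")
        if sum(self.parent_total(p, taxonomy) for p in ParentCategory) != n:
            raise IntegrityError("parent totals do not sum to n")

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a DataFrame: one row per category, Total/High/Unclear/Low."""
        rows = []
        for c in CategoryId:
            rows.append({
                "category": c.value,
                "Total": self.category_total(c),
                **{j.value.title(): self.cell(c, j) for j in JUDGMENT_ORDER},
            })
        return pd.DataFrame(rows).set_index("category")


def build_crosstab(trials: Sequence[ClassifiedTrial]) -> CrossTab:
    """Count assessed trials into the category x judgment cross-tabulation."""
    cells: dict[tuple[CategoryId, Judgment], int] = {
        (c, j): 0 for c in CategoryId for j in Judgment
    }
    for t in trials:
        cells[(t.category, t.observed)] += 1
    return CrossTab(cells=cells)


@dataclass(frozen=True)
class ConcordanceSummary:
    """All discordance summaries derived from one cross-tabulation."""

    overall: GroupStat
    per_judgment: Mapping[Judgment, GroupStat]
    per_parent: Mapping[ParentCategory, GroupStat]
    per_category: Mapping[CategoryId, GroupStat]
    strict_handbook: bool = False

    @property
    def n(self) -> int:
        return self.overall.total

    def to_dict(self) -> dict:
        def stat(s: GroupStat) -> dict:
            return {
                "total": s.total,
                "discordant": s.discordant,
                "discordant_percent_1dp": s.percent_1dp,
                "discordant_percent": s.percent_int,
            }

        return {
            "n": self.n,
            "strict_handbook": self.strict_handbook,
            "overall": stat(self.overall),
            "per_judgment": {j.value: stat(s) for j, s in self.per_judgment.items()},
            "per_parent": {p.value: stat(s) for p, s in self.per_parent.items()},
            "per_category": {c.value: stat(s) for c, s in self.per_category.items()},
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def summarize(
    crosstab: CrossTab, taxonomy: Taxonomy | None = None
) -> ConcordanceSummary:
    """Derive every discordance summary from a cross-tabulation.

    The discordant count within observed judgment j is the number of trials
    judged j whose parent category does not expect j; per-category and
    per-parent stats count members judged anything other than the expected
    judgment.
    """
    taxonomy = taxonomy or build_taxonomy()
    crosstab.validate(taxonomy)

    def cat_stat(c: CategoryId) -> GroupStat:
        total = crosstab.category_total(c)
        expected = taxonomy.expected_judgment(c)
        return GroupStat(total=total, discordant=total - crosstab.cell(c, expected))

    per_category = {c: cat_stat(c) for c in CategoryId}
    per_parent = {}
    for p in ParentCategory:
        members = taxonomy.members_of(p)
        per_parent[p] = GroupStat(
            total=sum(per_category[c].total for c in members),
            discordant=sum(per_category[c].discordant for c in members),
        )
    per_judgment = {}
    for j in Judgment:
        total = crosstab.judgment_total(j)
        concordant = sum(
            crosstab.cell(c, j)
            for c in CategoryId
            if taxonomy.expected_judgment(c) == j
        )
        per_judgment[j] = GroupStat(total=total, discordant=total - concordant)

    overall = GroupStat(
        total=crosstab.n,
        discordant=sum(s.discordant for s in per_judgment.values()),
    )
    # cross-check the two aggregation routes
    if overall.discordant != sum(s.discordant for s in per_parent.values()):
        raise IntegrityError("per-judgment and per-parent discordance disagree")
    return ConcordanceSummary(
        overall=overall,
        per_judgment=per_judgment,
        per_parent=per_parent,
        per_category=per_category,
        strict_handbook=taxonomy.strict_handbook,
    )


def summarize_from_counts(
    cells: Mapping[tuple[CategoryId, Judgment], int],
    strict_handbook: bool = False,
) -> ConcordanceSummary:
    """Summarise directly from explicit 19 x 3 cell counts.

    Equivalent to ``summarize(build_crosstab(trials))`` for any corpus
    realising those counts; this is the worked-example entry point for
    auditing a published cross-tabulation without the underlying rows.
    """
    return summarize(
        CrossTab.from_counts(cells), build_taxonomy(strict_handbook=strict_handbook)
    )


def _fmt_cell(count: int, percent: float | None) -> str:
    pct = "NA" if percent is None else f"{percent:.1f}"
    return f"{count:,} ({pct})"


def render_table(crosstab: CrossTab, taxonomy: Taxonomy | None = None) -> str:
    """Render the cross-tabulation as an aligned text table.

    Layout mirrors the canonical audit report: one row per parent category
    (annotated with its expected judgment), indented member-category rows
    whose total percentage is the share of the parent, judgment columns in
    the order Total / High / Unclear / Low with row percentages at one
    decimal, and a grand-total row.
    """
    taxonomy = taxonomy or build_taxonomy()
    crosstab.validate(taxonomy)
    n = crosstab.n

    header = ["Category", "Total, N (%)", "High, N (%)", "Unclear, N (%)", "Low, N (%)"]
    rows: list[list[str]] = []
    for p in ParentCategory:
        p_total = crosstab.parent_total(p, taxonomy)
        expected = taxonomy.expected_of(p).value.lower()
        rows.append([
            f"{taxonomy.label(p)} ({expected} risk)",
            _fmt_cell(p_total, None if n == 0 else round(100.0 * p_total / n, 1)),
            *[
                _fmt_cell(
                    crosstab.parent_cell(p, j, taxonomy),
                    None if p_total == 0
                    else round(100.0 * crosstab.parent_cell(p, j, taxonomy) / p_total, 1),
                )
                for j in JUDGMENT_ORDER
            ],
        ])
        for c in taxonomy.members_of(p):
            c_total = crosstab.category_total(c)
            rows.append([
                f"  {taxonomy.label(c)}",
                _fmt_cell(
                    c_total,
                    None if p_total == 0 else round(100.0 * c_total / p_total, 1),
                ),
                *[_fmt_cell(crosstab.cell(c, j), crosstab.row_percent(c, j))
                  for j in JUDGMENT_ORDER],
            ])
    rows.append([
        "Total",
        _fmt_cell(n, 100.0 if n else None),
        *[
            _fmt_cell(
                crosstab.judgment_total(j),
                None if n == 0 else round(100.0 * crosstab.judgment_total(j) / n, 1),
            )
            for j in JUDGMENT_ORDER
        ],
    ])

    widths = [max(len(header[i]), *(len(r[i]) for r in rows)) for i in range(len(header))]

    def fmt_row(cols: Sequence[str]) -> str:
        first = cols[0].ljust(widths[0])
        rest = [c.rjust(widths[i + 1]) for i, c in enumerate(cols[1:])]
        return "  ".join([first, *rest]).rstrip()

    lines = [fmt_row(header), fmt_row(["-" * w for w in widths])]
    lines.extend(fmt_row(r) for r in rows)
    return "\n".join(lines) + "\n"
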
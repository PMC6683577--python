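"""Synthetic RoB corpora with a configurable category x judgment structure.

No public accession of Cochrane RoB tables exists (the source pages are
paywalled), so every pipeline stage is exercised against generated corpora
instead.  The generator emulates the *joint* distribution of comment
category and authors' judgment observed in the reference audit of 10,103
trials, plus the excluded-record pathologies that audit encountered
(customised judgments, missing domains or whole RoB tables, empty or "N/A"
supports, duplicated entries).

Two allocation modes:

* ``EXACT_ALLOCATION`` — cell counts are the largest-remainder apportionment
  of joint x n_trials (ties broken in canonical cell order), so the default
  configuration reproduces the reference cross-tabulation cell for cell;
* ``MULTINOMIAL`` — cells drawn once from a seeded multinomial, for
  stochastic stress tests.

Draw order from the single seeded stream is fixed (cell counts only; support
texts cycle deterministically through each category's templates and
pathological records are appended in fixed reason order), so a seed pins the
corpus byte for byte.  Trials are dealt round-robin to reviews; pathological
studies go to a dedicated block of reviews that consequently lose all their
studies, reproducing review-level exclusion accounting.  The true
per-review study-count distribution of real corpora is not emulated (noted
in the manifest).
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classifier import RuleSet, classify_support, default_ruleset
from .ingest import RoBEntry
from .reference import (
    DEFAULT_PATHOLOGY_COUNTS,
    REFERENCE_CELL_COUNTS,
    REFERENCE_N,
    REFERENCE_N_EXCLUDED_REVIEWS,
    REFERENCE_N_REVIEWS,
)
from .taxonomy import CategoryId, Judgment

__all__ = [
    "SyntheticConfig",
    "SyntheticCorpusManifest",
    "default_config",
    "allocate_exact",
    "generate_entries",
    "generate_corpus",
    "write_fixture_html",
]

# Canonical cell order: categories in report row order, judgments High/Unclear/Low.
CELL_ORDER: tuple[tuple[CategoryId, Judgment], ...] = tuple(
    (c, j) for c in CategoryId for j in (Judgment.HIGH, Judgment.UNCLEAR, Judgment.LOW)
)

# Pathologies the generator can realise, in emission order.
_GENERATABLE_PATHOLOGIES = (
    "CUSTOMISED_JUDGMENT",
    "DOMAIN_MISSING",
    "ROB_TABLE_MISSING",
    "EMPTY_SUPPORT",
    "DUPLICATE_ENTRY",
)

SEQUENCE_GENERATION_DOMAIN = "Random sequence generation (selection bias)"
_OTHER_DOMAIN = "Allocation concealment (selection bias)"
_CUSTOM_JUDGMENTS = ("Moderate risk", "Moderate", "Some concerns")
_EMPTY_SUPPORTS = ("", "N/A", "n/a", "Not applicable")


class ConfigError(ValueError):
    """Synthetic configuration violating its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of one synthetic corpus."""

    n_trials: int
    n_reviews: int
    joint: Mapping[tuple[CategoryId, Judgment], float]
    mode: str = "EXACT_ALLOCATION"  # or MULTINOMIAL
    pathology_counts: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0
    templates: Mapping[CategoryId, tuple[str, ...]] | None = None
    n_pathology_reviews: int = REFERENCE_N_EXCLUDED_REVIEWS

    def resolved_templates(self) -> Mapping[CategoryId, tuple[str, ...]]:
        return self.templates if self.templates is not None else default_ruleset().templates

    def validate(self, rules: RuleSet | None = None) -> None:
        if self.n_trials <= 0 or self.n_reviews <= 0:
            raise ConfigError("n_trials and n_reviews must be positive")
        if self.mode not in ("EXACT_ALLOCATION", "MULTINOMIAL"):
            raise ConfigError(f"unknown mode: {self.mode!r}")
        total = sum(self.joint.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"joint probabilities sum to {total!r}, not 1")
        if any(p < 0 for p in self.joint.values()):
            raise ConfigError("joint probabilities must be nonnegative")
        for reason, count in self.pathology_counts.items():
            if reason not in _GENERATABLE_PATHOLOGIES:
                raise ConfigError(f"cannot generate pathology {reason!r}")
            if count < 0:
                raise ConfigError(f"negative pathology count for {reason}")
        templates = self.resolved_templates()
        rules = rules or default_ruleset()
        for (c, _j), p in self.joint.items():
            if p > 0:
                ts = templates.get(CategoryId(c), ())
                if not ts:
                    raise ConfigError(f"no template for category {CategoryId(c).value}")
                for t in ts:
                    got = classify_support(t, rules).category
                    if got is not CategoryId(c):
                        raise ConfigError(
                            f"template for {CategoryId(c).value} misroutes to "
                            f"{got.value}: {t!r}"
                        )


@dataclass
class SyntheticCorpusManifest:
    seed: int
    mode: str
    n_trials: int
    n_reviews: int
    cell_counts: dict[str, int]
    pathology_counts: dict[str, int]
    files: list[str] = field(default_factory=list)
    notes: str = (
        "trials dealt round-robin to reviews; per-review study-count "
        "distribution is a stand-in, not an emulation of real corpora"
    )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mode": self.mode,
            "n_trials": self.n_trials,
            "n_reviews": self.n_reviews,
            "cell_counts": self.cell_counts,
            "pathology_counts": self.pathology_counts,
            "files": self.files,
            "notes": self.notes,
        }


def default_config(seed: int = 0, mode: str = "EXACT_ALLOCATION") -> SyntheticConfig:
    """The reference-audit conditions: n=10,103 trials in 704 reviews, the
    published joint category x judgment distribution, and the published
    exclusion pathologies (19 + 96 + 16 + 56 = 187)."""
    joint = {
        cell: REFERENCE_CELL_COUNTS[cell] / REFERENCE_N for cell in CELL_ORDER
    }
    return SyntheticConfig(
        n_trials=REFERENCE_N,
        n_reviews=REFERENCE_N_REVIEWS,
        joint=joint,
        mode=mode,
        pathology_counts=dict(DEFAULT_PATHOLOGY_COUNTS),
        seed=seed,
    )


def allocate_exact(
    joint: Mapping[tuple[CategoryId, Judgment], float], n: int
) -> dict[tuple[CategoryId, Judgment], int]:
    """Largest-remainder apportionment of n trials over the joint cells.

    Each cell first receives floor(n * p); remaining trials go to the cells
    with the largest fractional parts, earlier canonical order winning ties.
    """
    quotas = [(cell, n * joint.get(cell, 0.0)) for cell in CELL_ORDER]
    counts = {cell: int(np.floor(q)) for cell, q in quotas}
    short = n - sum(counts.values())
    remainders = sorted(
        ((q - np.floor(q), -i) for i, (cell, q) in enumerate(quotas)),
        reverse=True,
    )
    for _frac, neg_i in remainders[:short]:
        counts[CELL_ORDER[-neg_i]] += 1
    return counts


def _realise_cells(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict[tuple[CategoryId, Judgment], int]:
    if config.mode == "EXACT_ALLOCATION":
        return allocate_exact(config.joint, config.n_trials)
    probs = np.array([config.joint.get(cell, 0.0) for cell in CELL_ORDER], dtype=float)
    probs = probs / probs.sum()
    draw = rng.multinomial(config.n_trials, probs)
    return {cell: int(k) for cell, k in zip(CELL_ORDER, draw)}


_JUDGMENT_TEXT = {
    Judgment.LOW: "Low risk",
    Judgment.UNCLEAR: "Unclear risk",
    Judgment.HIGH: "High risk",
}


def generate_entries(
    config: SyntheticConfig,
) -> tuple[list[RoBEntry], SyntheticCorpusManifest]:
    """Generate the corpus rows (in memory) plus its manifest.

    Clean trials are emitted cell by cell in canonical order, supports
    cycling through the category's templates; pathological studies follow in
    fixed reason order, assigned to a dedicated block of reviews.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cells = _realise_cells(config, rng)
    templates = config.resolved_templates()

    entries: list[RoBEntry] = []
    template_cursor: dict[CategoryId, int] = {}
    study_no = 0
    trial_no = 0
    for (cat, judg) in CELL_ORDER:
        for _ in range(cells.get((cat, judg), 0)):
            study_no += 1
            review = f"R{(trial_no % config.n_reviews) + 1:04d}"
            trial_no += 1
            ts = templates[cat]
            k = template_cursor.get(cat, 0)
            template_cursor[cat] = k + 1
            entries.append(RoBEntry.from_fields(
                review_id=review,
                study_id=f"S{study_no:05d}",
                domain=SEQUENCE_GENERATION_DOMAIN,
                judgment=_JUDGMENT_TEXT[judg],
                support=ts[k % len(ts)],
                study_design="RCT",
            ))

    path_no = 0
    nd_templates = templates[CategoryId.NOT_DESCRIBED]
    for reason in _GENERATABLE_PATHOLOGIES:
        for i in range(config.pathology_counts.get(reason, 0)):
            study_no += 1
            review = f"XR{(path_no % max(config.n_pathology_reviews, 1)) + 1:03d}"
            path_no += 1
            sid = f"S{study_no:05d}"
            if reason == "CUSTOMISED_JUDGMENT":
                entries.append(RoBEntry.from_fields(
                    review, sid, SEQUENCE_GENERATION_DOMAIN,
                    _CUSTOM_JUDGMENTS[i % len(_CUSTOM_JUDGMENTS)],
                    nd_templates[i % len(nd_templates)], "RCT",
                ))
            elif reason == "DOMAIN_MISSING":
                entries.append(RoBEntry.from_fields(
                    review, sid, _OTHER_DOMAIN, "Low risk",
                    "Inert placeholder row for a non-sequence-generation domain.",
                    "RCT",
                ))
            elif reason == "ROB_TABLE_MISSING":
                # interchange convention: empty domain marks a study w/o RoB table
                entries.append(RoBEntry.from_fields(review, sid, "", "", "", "RCT"))
            elif reason == "EMPTY_SUPPORT":
                entries.append(RoBEntry.from_fields(
                    review, sid, SEQUENCE_GENERATION_DOMAIN, "Unclear risk",
                    _EMPTY_SUPPORTS[i % len(_EMPTY_SUPPORTS)], "RCT",
                ))
            elif reason == "DUPLICATE_ENTRY":
                row = RoBEntry.from_fields(
                    review, sid, SEQUENCE_GENERATION_DOMAIN, "Low risk",
                    nd_templates[i % len(nd_templates)], "RCT",
                )
                entries.extend([row, row])

    manifest = SyntheticCorpusManifest(
        seed=config.seed,
        mode=config.mode,
        n_trials=config.n_trials,
        n_reviews=config.n_reviews,
        cell_counts={
            f"{c.value}|{j.value}": cells.get((c, j), 0) for (c, j) in CELL_ORDER
        },
        pathology_counts={
            r: config.pathology_counts.get(r, 0) for r in _GENERATABLE_PATHOLOGIES
        },
    )
    return entries, manifest


def write_fixture_html(entries: Sequence[RoBEntry], target) -> None:
    """Write entries as the HTML fixture dialect.

    Consecutive rows with the same (review, study) form one study section; a
    repeated domain within a study starts a fresh (duplicate) section, and a
    study whose only row has an empty domain is written without a
    "Risk of bias" table.
    """
    # split into per-study row runs, preserving duplicates as separate runs
    runs: list[tuple[str, str, str | None, list[RoBEntry]]] = []
    for e in entries:
        if runs:
            rid, sid, _d, rows = runs[-1]
            same = (rid, sid) == (e.review_id, e.study_id)
            dup = same and any(r.domain_name == e.domain_name for r in rows)
            if same and not dup:
                rows.append(e)
                continue
        runs.append((e.review_id, e.study_id, e.study_design, [e]))

    esc = html.escape
    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'>"
        "<title>Characteristics of included studies (fixture)</title></head><body>",
    ]
    current_review = None
    for rid, sid, design, rows in runs:
        if rid != current_review:
            if current_review is not None:
                parts.append("</div>")
            parts.append(f"<div class='review' id='{esc(rid)}'><h1>Review {esc(rid)}</h1>")
            current_review = rid
        design_attr = f" data-study-design='{esc(design)}'" if design else ""
        parts.append(f"<div class='study'{design_attr}><h2>{esc(sid)}</h2>")
        parts.append(
            "<table class='characteristics'><tr><th>Methods</th>"
            "<td>Randomised controlled trial (fixture)</td></tr></table>"
        )
        real_rows = [r for r in rows if r.domain_name.strip()]
        if real_rows:
            parts.append("<h3>Risk of bias</h3>")
            parts.append(
                "<table class='rob'><tr><th>Bias</th><th>Authors' judgement</th>"
                "<th>Support for judgement</th></tr>"
            )
            for r in real_rows:
                parts.append(
                    f"<tr><td>{esc(r.domain_name)}</td><td>{esc(r.judgment_raw)}</td>"
                    f"<td>{esc(r.support_text)}</td></tr>"
                )
            parts.append("</table>")
        parts.append("</div>")
    if current_review is not None:
        parts.append("</div>")
    parts.append("</body></html>")

    text = "\n".join(parts) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text, encoding="utf-8")
    else:
        target.write(text)


def generate_corpus(
    config: SyntheticConfig,
    outdir,
    formats: Sequence[str] = ("csv",),
) -> SyntheticCorpusManifest:
    """Generate a corpus and write it under ``outdir``.

    ``formats`` is any subset of {"csv", "jsonl", "html"}; a manifest.json is
    always written.  Identical config and seed give byte-identical files.
    """
    from .ingest import write_interchange  # local import to keep module load light

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries, manifest = generate_entries(config)
    for fmt in formats:
        if fmt == "csv":
            path = outdir / "corpus.csv"
            write_interchange(entries, path, dialect="csv")
        elif fmt == "jsonl":
            path = outdir / "corpus.jsonl"
            write_interchange(entries, path, dialect="jsonl")
        elif fmt == "html":
            path = outdir / "corpus.html"
            write_fixture_html(entries, path)
        else:
            raise ValueError(f"unknown format: {fmt!r}")
        manifest.files.append(path.name)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=2) + "\n", encoding="utf-8")
    manifest.files.append(manifest_path.name)
    return manifest
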
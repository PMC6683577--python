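"""Deterministic keyword classification of support-for-judgment comments.

Each nonempty support comment is assigned exactly one of the 19 taxonomy
categories by tiered first-match-wins keyword rules:

1. **high** tier — indicators of a systematic non-random component or a
   broken randomisation (quasi-random allocation, incomplete/erroneous
   procedures, allocation by judgment/preference/availability).  Any such
   indicator taints the whole comment, so this tier runs first.
2. **low** tier — explicit adequate methods (random number table, computer/
   software, IVRS, minimisation, bare random number generator, web-based,
   coin, lots, shuffled cards/envelopes, dice).
3. **not_described** tier — comments that mention some procedural aspect
   (blocks/stratification, envelopes, central randomisation, baseline
   (im)balance) without describing the actual sequence-generation method,
   plus explicit "not stated"-style phrases.
4. fallback — anything else is NOT_DESCRIBED (the residual definition of
   that category: whatever fits none of the 13 informative categories).

Rules are plain data (regex patterns in a YAML document) so they can be
inspected, versioned, exported and reloaded without behaviour change; every
classification carries a full rule trace for audit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .ingest import Corpus, RoBEntry
from .taxonomy import CategoryId, Judgment, ParentCategory, Taxonomy, build_taxonomy

__all__ = [
    "Rule",
    "RuleSet",
    "CategoryAssignment",
    "ClassifiedTrial",
    "default_ruleset",
    "load_ruleset",
    "save_ruleset",
    "classify_support",
    "classify_corpus",
]

FALLBACK = "FALLBACK"


@dataclass(frozen=True)
class Rule:
    """One pattern rule: fires when every ``all`` regex matches and no
    ``none`` regex does (case-insensitive search on normalised text)."""

    category: CategoryId
    all_patterns: tuple[str, ...]
    none_patterns: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(
            self, "_all_re", tuple(re.compile(p, re.IGNORECASE) for p in self.all_patterns)
        )
        object.__setattr__(
            self, "_none_re", tuple(re.compile(p, re.IGNORECASE) for p in self.none_patterns)
        )

    def matches(self, text: str) -> bool:
        return all(r.search(text) for r in self._all_re) and not any(
            r.search(text) for r in self._none_re
        )

    @property
    def pattern_repr(self) -> str:
        return " && ".join(self.all_patterns) + (
            " !! " + " || ".join(self.none_patterns) if self.none_patterns else ""
        )


@dataclass(frozen=True)
class RuleSet:
    """Ordered tiers of rules plus the synthetic support-text templates."""

    tiers: tuple[tuple[str, tuple[Rule, ...]], ...]
    templates: Mapping[CategoryId, tuple[str, ...]]
    version: str = "unversioned"

    def iter_rules(self) -> Iterable[tuple[str, Rule]]:
        for tier_name, rules in self.tiers:
            for rule in rules:
                yield tier_name, rule

    def categories_with_rules(self) -> set[CategoryId]:
        return {rule.category for _t, rule in self.iter_rules()}

    def to_config(self) -> dict:
        """Plain-dict form of the rules document (inverse of ``_from_config``)."""
        return {
            "version": self.version,
            "tiers": [
                {
                    "name": tier_name,
                    "rules": [
                        {
                            "category": rule.category.value,
                            "all": list(rule.all_patterns),
                            **(
                                {"none": list(rule.none_patterns)}
                                if rule.none_patterns else {}
                            ),
                        }
                        for rule in rules
                    ],
                }
                for tier_name, rules in self.tiers
            ],
            "templates": {
                c.value: list(ts) for c, ts in self.templates.items()
            },
        }


@dataclass(frozen=True)
class CategoryAssignment:
    """Result of classifying one support comment, with full audit trace."""

    category: CategoryId
    matched_tier: str
    matched_pattern: str  # FALLBACK when no rule fired
    trace: tuple[str, ...] = ()

    @property
    def is_fallback(self) -> bool:
        return self.matched_pattern == FALLBACK


@dataclass
class ClassifiedTrial:
    """A corpus entry with its category, expected and observed judgments.

    ``concordant`` is left None by the classifier and set by the
    concordance stage.
    """

    entry: RoBEntry
    category: CategoryId
    parent: ParentCategory
    expected: Judgment
    observed: Judgment
    concordant: bool | None = None
    matched_tier: str = ""
    matched_pattern: str = FALLBACK
    trace: tuple[str, ...] = ()


def _from_config(cfg: Mapping, version_fallback: str = "unversioned") -> RuleSet:
    tiers = []
    for tier in cfg.get("tiers", []):
        rules = tuple(
            Rule(
                category=CategoryId(r["category"]),
                all_patterns=tuple(r["all"]),
                none_patterns=tuple(r.get("none", ())),
            )
            for r in tier.get("rules", [])
        )
        tiers.append((tier["name"], rules))
    templates = {
        CategoryId(c): tuple(ts) for c, ts in cfg.get("templates", {}).items()
    }
    missing = [c.value for c in CategoryId if c not in templates]
    if missing:
        raise ValueError(f"rules document lacks templates for: {', '.join(missing)}")
    return RuleSet(
        tiers=tuple(tiers),
        templates=templates,
        version=str(cfg.get("version", version_fallback)),
    )


_DEFAULT: RuleSet | None = None


def default_ruleset() -> RuleSet:
    """The built-in rules, loaded from the packaged YAML document."""
    global _DEFAULT
    if _DEFAULT is None:
        text = resources.files("robaudit").joinpath("data/default_rules.yaml").read_text(
            encoding="utf-8"
        )
        _DEFAULT = _from_config(yaml.safe_load(text))
    return _DEFAULT


def load_ruleset(path) -> RuleSet:
    """Load rules from a YAML document (same schema as the built-in one)."""
    with open(path, "r", encoding="utf-8") as fh:
        return _from_config(yaml.safe_load(fh))


def save_ruleset(rules: RuleSet, path) -> None:
    """Write a rules document that reloads to behaviourally identical rules."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(rules.to_config(), fh, sort_keys=False, allow_unicode=True)


_WS = re.compile(r"\s+")


def classify_support(support_text: str, rules: RuleSet | None = None) -> CategoryAssignment:
    """Assign one category to a nonempty support comment.

    First matching rule in tier order wins; a comment matching nothing is
    NOT_DESCRIBED with ``matched_pattern="FALLBACK"``.  Deterministic:
    identical text and rules always give identical output.
    """
    if not support_text or not support_text.strip():
        raise ValueError("support_text must be nonempty (empty supports are excluded upstream)")
    if rules is None:
        rules = default_ruleset()
    text = _WS.sub(" ", support_text).strip()
    trace: list[str] = []
    for tier_name, rule in rules.iter_rules():
        trace.append(f"{tier_name}:{rule.category.value}")
        if rule.matches(text):
            return CategoryAssignment(
                category=rule.category,
                matched_tier=tier_name,
                matched_pattern=rule.pattern_repr,
                trace=tuple(trace),
            )
    return CategoryAssignment(
        category=CategoryId.NOT_DESCRIBED,
        matched_tier="fallback",
        matched_pattern=FALLBACK,
        trace=tuple(trace),
    )


def classify_corpus(
    corpus: Corpus | Sequence[RoBEntry],
    rules: RuleSet | None = None,
    taxonomy: Taxonomy | None = None,
) -> list[ClassifiedTrial]:
    """Classify every included entry of an exclusion-filtered corpus.

    Returns one ClassifiedTrial per entry, order preserved, carrying the
    category, its parent, the Handbook-expected judgment and the full rule
    trace.  The concordance flag is left unset for the concordance stage.
    """
    if rules is None:
        rules = default_ruleset()
    if taxonomy is None:
        taxonomy = build_taxonomy()
    entries = corpus.included if isinstance(corpus, Corpus) else list(corpus)
    out: list[ClassifiedTrial] = []
    for entry in entries:
        if entry.judgment is None:
            raise ValueError(
                f"entry {entry.review_id}/{entry.study_id} reached the classifier "
                f"with a non-standard judgment {entry.judgment_raw!r}; "
                "exclusion filtering must run first"
            )
        assignment = classify_support(entry.support_text, rules)
        parent = taxonomy.parent_of(assignment.category)
        out.append(ClassifiedTrial(
            entry=entry,
            category=assignment.category,
            parent=parent,
            expected=taxonomy.expected_of(parent),
            observed=entry.judgment,
            concordant=None,
            matched_tier=assignment.matched_tier,
            matched_pattern=assignment.matched_pattern,
            trace=assignment.trace,
        ))
    return out
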
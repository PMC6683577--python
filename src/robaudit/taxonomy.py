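"""Closed category system for supports-for-judgment of random sequence generation.

The Cochrane risk-of-bias (RoB) tool asks review authors to judge the random
sequence generation domain of every included trial as low, unclear or high
risk of selection bias, and to justify the judgment with a free-text "support
for judgement" comment.  The Cochrane Handbook (Table 8.5.d) maps described
randomisation methods to an expected judgment; this module encodes the
resulting closed taxonomy used throughout the package:

* 19 comment categories (what the support text actually describes),
* grouped into 5 parent categories,
* each parent carrying a single Handbook-expected judgment.

The 13 categories whose parent expects LOW or HIGH are the "informative"
categories; every comment that fits none of them falls under the
method-not-described parent, which expects UNCLEAR.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

__all__ = [
    "Judgment",
    "CategoryId",
    "ParentCategory",
    "Taxonomy",
    "build_taxonomy",
    "expected_judgment",
]


class Judgment(str, enum.Enum):
    """The three standard RoB judgment values.

    Anything else found in a source table ("moderate", "some concerns", ...)
    is a customised judgment and never enters this enum; the ingest layer
    keeps such strings as raw text and excludes the study.
    """

    LOW = "LOW"
    UNCLEAR = "UNCLEAR"
    HIGH = "HIGH"


class CategoryId(str, enum.Enum):
    """The 19 support-comment categories, in canonical report row order."""

    # random number table parent
    RANDOM_NUMBER_TABLE = "RANDOM_NUMBER_TABLE"
    # computer / software / internet parent
    COMPUTER_SOFTWARE_GENERATED = "COMPUTER_SOFTWARE_GENERATED"
    IVRS = "IVRS"
    MINIMISATION = "MINIMISATION"
    RNG_NO_COMPUTER = "RNG_NO_COMPUTER"
    WEB_BASED = "WEB_BASED"
    # mechanical parent
    COIN_TOSSING = "COIN_TOSSING"
    DRAWING_LOTS = "DRAWING_LOTS"
    SHUFFLING_CARDS_ENVELOPES = "SHUFFLING_CARDS_ENVELOPES"
    THROWING_DICE = "THROWING_DICE"
    # incomplete / inappropriate parent
    QUASI_RANDOM = "QUASI_RANDOM"
    INCOMPLETE_ERRONEOUS = "INCOMPLETE_ERRONEOUS"
    JUDGMENT_PREFERENCE_AVAILABILITY = "JUDGMENT_PREFERENCE_AVAILABILITY"
    # method not described parent
    NOT_DESCRIBED = "NOT_DESCRIBED"
    BLOCK_OR_STRATIFICATION_ONLY = "BLOCK_OR_STRATIFICATION_ONLY"
    ENVELOPES_NO_METHOD = "ENVELOPES_NO_METHOD"
    CENTRAL_RANDOMISATION_NO_METHOD = "CENTRAL_RANDOMISATION_NO_METHOD"
    BASELINE_IMBALANCE = "BASELINE_IMBALANCE"
    BASELINE_BALANCE = "BASELINE_BALANCE"


class ParentCategory(str, enum.Enum):
    """The 5 parent categories; each carries one Handbook-expected judgment."""

    RANDOM_NUMBER_TABLE_P = "RANDOM_NUMBER_TABLE_P"
    COMPUTER_SOFTWARE_INTERNET = "COMPUTER_SOFTWARE_INTERNET"
    MECHANICAL = "MECHANICAL"
    INCOMPLETE_OR_INAPPROPRIATE = "INCOMPLETE_OR_INAPPROPRIATE"
    METHOD_NOT_DESCRIBED = "METHOD_NOT_DESCRIBED"


# Human-readable labels matching the canonical report layout verbatim.
CATEGORY_LABELS: Mapping[CategoryId, str] = MappingProxyType({
    CategoryId.RANDOM_NUMBER_TABLE: "Random number table",
    CategoryId.COMPUTER_SOFTWARE_GENERATED: "Computer/software generated",
    CategoryId.IVRS: "IVRS",
    CategoryId.MINIMISATION: "Minimisation",
    CategoryId.RNG_NO_COMPUTER: "Random number generator (without mention of computer)",
    CategoryId.WEB_BASED: "Web based",
    CategoryId.COIN_TOSSING: "Coin tossing",
    CategoryId.DRAWING_LOTS: "Drawing of lots",
    CategoryId.SHUFFLING_CARDS_ENVELOPES: "Shuffling cards or envelopes",
    CategoryId.THROWING_DICE: "Throwing dice",
    CategoryId.QUASI_RANDOM: "Quasi random",
    CategoryId.INCOMPLETE_ERRONEOUS: "Incomplete, erroneous randomisation",
    CategoryId.JUDGMENT_PREFERENCE_AVAILABILITY: "Judgment, preference, availability",
    CategoryId.NOT_DESCRIBED: "Not described",
    CategoryId.BLOCK_OR_STRATIFICATION_ONLY: "Block randomisation/stratification",
    CategoryId.ENVELOPES_NO_METHOD: "Envelopes",
    CategoryId.CENTRAL_RANDOMISATION_NO_METHOD:
        "Central randomisation (statistics department, pharmacy, third party)",
    CategoryId.BASELINE_IMBALANCE: "Baseline imbalance between groups",
    CategoryId.BASELINE_BALANCE: "Baseline balance between groups",
})

PARENT_LABELS: Mapping[ParentCategory, str] = MappingProxyType({
    ParentCategory.RANDOM_NUMBER_TABLE_P: "Random number table",
    ParentCategory.COMPUTER_SOFTWARE_INTERNET: "Randomisation via computer/software/internet",
    ParentCategory.MECHANICAL: "Mechanical method of randomisation",
    ParentCategory.INCOMPLETE_OR_INAPPROPRIATE: "Incomplete or inappropriate randomisation",
    ParentCategory.METHOD_NOT_DESCRIBED: "Method of randomisation was not described",
})

_PARENT_OF: Mapping[CategoryId, ParentCategory] = MappingProxyType({
    CategoryId.RANDOM_NUMBER_TABLE: ParentCategory.RANDOM_NUMBER_TABLE_P,
    CategoryId.COMPUTER_SOFTWARE_GENERATED: ParentCategory.COMPUTER_SOFTWARE_INTERNET,
    CategoryId.IVRS: ParentCategory.COMPUTER_SOFTWARE_INTERNET,
    CategoryId.MINIMISATION: ParentCategory.COMPUTER_SOFTWARE_INTERNET,
    CategoryId.RNG_NO_COMPUTER: ParentCategory.COMPUTER_SOFTWARE_INTERNET,
    CategoryId.WEB_BASED: ParentCategory.COMPUTER_SOFTWARE_INTERNET,
    CategoryId.COIN_TOSSING: ParentCategory.MECHANICAL,
    CategoryId.DRAWING_LOTS: ParentCategory.MECHANICAL,
    CategoryId.SHUFFLING_CARDS_ENVELOPES: ParentCategory.MECHANICAL,
    CategoryId.THROWING_DICE: ParentCategory.MECHANICAL,
    CategoryId.QUASI_RANDOM: ParentCategory.INCOMPLETE_OR_INAPPROPRIATE,
    CategoryId.INCOMPLETE_ERRONEOUS: ParentCategory.INCOMPLETE_OR_INAPPROPRIATE,
    CategoryId.JUDGMENT_PREFERENCE_AVAILABILITY: ParentCategory.INCOMPLETE_OR_INAPPROPRIATE,
    CategoryId.NOT_DESCRIBED: ParentCategory.METHOD_NOT_DESCRIBED,
    CategoryId.BLOCK_OR_STRATIFICATION_ONLY: ParentCategory.METHOD_NOT_DESCRIBED,
    CategoryId.ENVELOPES_NO_METHOD: ParentCategory.METHOD_NOT_DESCRIBED,
    CategoryId.CENTRAL_RANDOMISATION_NO_METHOD: ParentCategory.METHOD_NOT_DESCRIBED,
    CategoryId.BASELINE_IMBALANCE: ParentCategory.METHOD_NOT_DESCRIBED,
    CategoryId.BASELINE_BALANCE: ParentCategory.METHOD_NOT_DESCRIBED,
})

_EXPECTED_OF: Mapping[ParentCategory, Judgment] = MappingProxyType({
    ParentCategory.RANDOM_NUMBER_TABLE_P: Judgment.LOW,
    ParentCategory.COMPUTER_SOFTWARE_INTERNET: Judgment.LOW,
    ParentCategory.MECHANICAL: Judgment.LOW,
    ParentCategory.INCOMPLETE_OR_INAPPROPRIATE: Judgment.HIGH,
    ParentCategory.METHOD_NOT_DESCRIBED: Judgment.UNCLEAR,
})


@dataclass(frozen=True)
class Taxonomy:
    """Immutable category system: membership, parent grouping, expected judgments.

    ``strict_handbook`` moves the "random number generator (without mention of
    computer)" category from the computer/software/internet parent (expected
    LOW) into the method-not-described parent (expected UNCLEAR).  A bare
    mention of a random number generator does not, under a strict Handbook
    reading, confirm an electronic truly-random process; the default keeps it
    in the computer parent, which is the convention used for the headline
    numbers, and the strict flag is the documented sensitivity analysis.
    """

    parent_map: Mapping[CategoryId, ParentCategory]
    expected_map: Mapping[ParentCategory, Judgment]
    strict_handbook: bool = False

    @property
    def categories(self) -> tuple[CategoryId, ...]:
        return tuple(CategoryId)

    @property
    def parents(self) -> tuple[ParentCategory, ...]:
        return tuple(ParentCategory)

    def parent_of(self, category: CategoryId) -> ParentCategory:
        try:
            return self.parent_map[CategoryId(category)]
        except (KeyError, ValueError) as exc:
            raise KeyError(f"unknown category: {category!r}") from exc

    def expected_of(self, parent: ParentCategory) -> Judgment:
        try:
            return self.expected_map[ParentCategory(parent)]
        except (KeyError, ValueError) as exc:
            raise KeyError(f"unknown parent category: {parent!r}") from exc

    def expected_judgment(self, category: CategoryId) -> Judgment:
        """Handbook-expected judgment for a comment category (via its parent)."""
        return self.expected_of(self.parent_of(category))

    def members_of(self, parent: ParentCategory) -> tuple[CategoryId, ...]:
        parent = ParentCategory(parent)
        return tuple(c for c in CategoryId if self.parent_map[c] is parent)

    def informative_categories(self) -> tuple[CategoryId, ...]:
        """The categories whose parent expects LOW or HIGH (13 by default)."""
        return tuple(
            c for c in CategoryId
            if self.expected_judgment(c) is not Judgment.UNCLEAR
        )

    def label(self, item: CategoryId | ParentCategory) -> str:
        if isinstance(item, CategoryId):
            return CATEGORY_LABELS[item]
        return PARENT_LABELS[ParentCategory(item)]

    def to_config(self) -> dict:
        """Plain-dict form for the human-editable YAML config document."""
        return {
            c.value: {
                "label": CATEGORY_LABELS[c],
                "parent": self.parent_of(c).value,
                "expected": self.expected_judgment(c).value,
            }
            for c in CategoryId
        }


def build_taxonomy(strict_handbook: bool = False) -> Taxonomy:
    """Construct the fixed taxonomy.

    Parameters
    ----------
    strict_handbook:
        Reassign RNG_NO_COMPUTER to the method-not-described parent
        (expected UNCLEAR) for the strict-Handbook sensitivity analysis.
    """
    parent_map = dict(_PARENT_OF)
    if strict_handbook:
        parent_map[CategoryId.RNG_NO_COMPUTER] = ParentCategory.METHOD_NOT_DESCRIBED
    return Taxonomy(
        parent_map=MappingProxyType(parent_map),
        expected_map=_EXPECTED_OF,
        strict_handbook=strict_handbook,
    )


def expected_judgment(category: CategoryId, strict_handbook: bool = False) -> Judgment:
    """Convenience wrapper: Handbook-expected judgment for ``category``."""
    return build_taxonomy(strict_handbook).expected_judgment(category)
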
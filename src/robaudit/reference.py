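"""Reference category-by-judgment counts from a large published audit.

A 2019 meta-epidemiological audit of Cochrane reviews classified the support
comments for the random sequence generation domain of 10,103 randomised trials
(704 reviews) into the 19-category taxonomy and cross-tabulated them against
the review authors' judgments.  The full 19 x 3 table is reproduced here; it
serves two purposes:

* the worked example for the concordance summariser (every headline
  discordance figure is a deterministic function of these 57 cells), and
* the default joint category x judgment distribution of the synthetic corpus
  generator, so end-to-end runs emulate a realistically structured corpus.

The same audit excluded 187 trials before analysis; the default pathology
counts below reproduce that exclusion accounting (19 customised judgments,
96 studies missing the sequence-generation domain, 16 missing the whole RoB
table, 56 with empty or "N/A" supports).
"""

from __future__ import annotations

from types import MappingProxyType
from typing import Mapping

from .taxonomy import CategoryId, Judgment

__all__ = [
    "REFERENCE_CELL_COUNTS",
    "REFERENCE_N",
    "REFERENCE_N_REVIEWS",
    "DEFAULT_PATHOLOGY_COUNTS",
    "REFERENCE_N_EXCLUDED_REVIEWS",
]

# Cells keyed (category, judgment); rows in canonical report order.
REFERENCE_CELL_COUNTS: Mapping[tuple[CategoryId, Judgment], int] = MappingProxyType({
    (CategoryId.RANDOM_NUMBER_TABLE, Judgment.HIGH): 11,
    (CategoryId.RANDOM_NUMBER_TABLE, Judgment.UNCLEAR): 31,
    (CategoryId.RANDOM_NUMBER_TABLE, Judgment.LOW): 841,

    (CategoryId.COMPUTER_SOFTWARE_GENERATED, Judgment.HIGH): 0,
    (CategoryId.COMPUTER_SOFTWARE_GENERATED, Judgment.UNCLEAR): 17,
    (CategoryId.COMPUTER_SOFTWARE_GENERATED, Judgment.LOW): 2442,

    (CategoryId.IVRS, Judgment.HIGH): 0,
    (CategoryId.IVRS, Judgment.UNCLEAR): 7,
    (CategoryId.IVRS, Judgment.LOW): 53,

    (CategoryId.MINIMISATION, Judgment.HIGH): 2,
    (CategoryId.MINIMISATION, Judgment.UNCLEAR): 8,
    (CategoryId.MINIMISATION, Judgment.LOW): 93,

    (CategoryId.RNG_NO_COMPUTER, Judgment.HIGH): 0,
    (CategoryId.RNG_NO_COMPUTER, Judgment.UNCLEAR): 0,
    (CategoryId.RNG_NO_COMPUTER, Judgment.LOW): 98,

    (CategoryId.WEB_BASED, Judgment.HIGH): 0,
    (CategoryId.WEB_BASED, Judgment.UNCLEAR): 4,
    (CategoryId.WEB_BASED, Judgment.LOW): 126,

    (CategoryId.COIN_TOSSING, Judgment.HIGH): 0,
    (CategoryId.COIN_TOSSING, Judgment.UNCLEAR): 1,
    (CategoryId.COIN_TOSSING, Judgment.LOW): 84,

    (CategoryId.DRAWING_LOTS, Judgment.HIGH): 4,
    (CategoryId.DRAWING_LOTS, Judgment.UNCLEAR): 12,
    (CategoryId.DRAWING_LOTS, Judgment.LOW): 185,

    (CategoryId.SHUFFLING_CARDS_ENVELOPES, Judgment.HIGH): 3,
    (CategoryId.SHUFFLING_CARDS_ENVELOPES, Judgment.UNCLEAR): 24,
    (CategoryId.SHUFFLING_CARDS_ENVELOPES, Judgment.LOW): 33,

    (CategoryId.THROWING_DICE, Judgment.HIGH): 0,
    (CategoryId.THROWING_DICE, Judgment.UNCLEAR): 0,
    (CategoryId.THROWING_DICE, Judgment.LOW): 13,

    (CategoryId.QUASI_RANDOM, Judgment.HIGH): 209,
    (CategoryId.QUASI_RANDOM, Judgment.UNCLEAR): 22,
    (CategoryId.QUASI_RANDOM, Judgment.LOW): 7,

    (CategoryId.INCOMPLETE_ERRONEOUS, Judgment.HIGH): 34,
    (CategoryId.INCOMPLETE_ERRONEOUS, Judgment.UNCLEAR): 7,
    (CategoryId.INCOMPLETE_ERRONEOUS, Judgment.LOW): 0,

    (CategoryId.JUDGMENT_PREFERENCE_AVAILABILITY, Judgment.HIGH): 21,
    (CategoryId.JUDGMENT_PREFERENCE_AVAILABILITY, Judgment.UNCLEAR): 3,
    (CategoryId.JUDGMENT_PREFERENCE_AVAILABILITY, Judgment.LOW): 2,

    (CategoryId.NOT_DESCRIBED, Judgment.HIGH): 69,
    (CategoryId.NOT_DESCRIBED, Judgment.UNCLEAR): 4272,
    (CategoryId.NOT_DESCRIBED, Judgment.LOW): 245,

    (CategoryId.BLOCK_OR_STRATIFICATION_ONLY, Judgment.HIGH): 2,
    (CategoryId.BLOCK_OR_STRATIFICATION_ONLY, Judgment.UNCLEAR): 219,
    (CategoryId.BLOCK_OR_STRATIFICATION_ONLY, Judgment.LOW): 458,

    (CategoryId.ENVELOPES_NO_METHOD, Judgment.HIGH): 3,
    (CategoryId.ENVELOPES_NO_METHOD, Judgment.UNCLEAR): 117,
    (CategoryId.ENVELOPES_NO_METHOD, Judgment.LOW): 127,

    (CategoryId.CENTRAL_RANDOMISATION_NO_METHOD, Judgment.HIGH): 1,
    (CategoryId.CENTRAL_RANDOMISATION_NO_METHOD, Judgment.UNCLEAR): 0,
    (CategoryId.CENTRAL_RANDOMISATION_NO_METHOD, Judgment.LOW): 123,

    (CategoryId.BASELINE_IMBALANCE, Judgment.HIGH): 6,
    (CategoryId.BASELINE_IMBALANCE, Judgment.UNCLEAR): 35,
    (CategoryId.BASELINE_IMBALANCE, Judgment.LOW): 0,

    (CategoryId.BASELINE_BALANCE, Judgment.HIGH): 0,
    (CategoryId.BASELINE_BALANCE, Judgment.UNCLEAR): 8,
    (CategoryId.BASELINE_BALANCE, Judgment.LOW): 21,
})

REFERENCE_N: int = sum(REFERENCE_CELL_COUNTS.values())  # 10,103
REFERENCE_N_REVIEWS: int = 704

# Exclusion pathologies of the reference corpus (primary reasons only).
DEFAULT_PATHOLOGY_COUNTS: Mapping[str, int] = MappingProxyType({
    "CUSTOMISED_JUDGMENT": 19,
    "DOMAIN_MISSING": 96,
    "ROB_TABLE_MISSING": 16,
    "EMPTY_SUPPORT": 56,
})

REFERENCE_N_EXCLUDED_REVIEWS: int = 14
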
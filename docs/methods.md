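# Methods

## The audit model

Each analysable record is one trial's random-sequence-generation row from a
Cochrane-style RoB table: an authors' judgment `J ∈ {low, unclear, high}`
and a free-text support comment. The audit is a deterministic function of
those two fields:

1. the comment is mapped to exactly one of 19 categories `c`;
2. `c` belongs to exactly one of 5 parent categories `P(c)`, and each parent
   carries one Handbook-expected judgment `E(P)`:
   random number table → low; computer/software/internet → low; mechanical →
   low; incomplete/inappropriate → high; method not described → unclear;
3. the judgment is *discordant* iff `J ≠ E(P(c))`.

Everything reported — overall discordance, discordance within each observed
judgment, per-parent adequacy, per-category row shares — is arithmetic on
the resulting 19 x 3 contingency table, so any published table of those 57
cells can be re-audited exactly via `summarize_from_counts` without
row-level data.

The assumption worth stating plainly: the *comment* is taken as the complete
evidence for the judgment. A judgment may have been right given information
the review authors saw but did not write down; the audit measures whether
the judgment is *supported as written*, which is also what a reader of the
review can verify.

## Classifier construction

The Handbook names the adequate (low-risk) methods and the inadequate
(high-risk) ones but publishes no keyword lists, so the rules here are a
reconstruction, shipped as data (`robaudit/data/default_rules.yaml`, regex
patterns, versioned) rather than code, and exportable/reloadable with
identical behaviour so rule changes are distinguishable from data changes.

Design choices that were genuinely open:

* **Tier order high > low > not-described > fallback.** The not-described
  parent is defined as the residual of the 13 informative categories, so its
  patterns must run last before the fallback; high-risk indicators run first
  on the view that any systematic non-random component ("alternate
  allocation by computer list") taints the whole comment.
* **Within-tier order is the canonical report row order, first match wins.**
  No ranking between subcategories is defined by the guidance itself, so a
  fixed order is chosen for determinism; a comment naming two adequate
  methods keeps the earlier row's category, and either choice would leave
  the parent — hence every audit figure — unchanged in almost all cases.
* **Envelope disambiguation.** "Shuffling cards or envelopes" (mechanical,
  low) requires a mechanical action word (shuffle/draw/toss/...) next to the
  cards/envelopes mention; a bare envelope mention is the not-described
  subcategory "Envelopes" (unclear). Both rows exist in the taxonomy, so the
  boundary must be explicit.
* **Baseline balance vs imbalance** are distinguished by explicit imbalance
  terms (imbalance / differed / not comparable / unequal); both live in the
  not-described parent, so the split never moves a parent-level figure.
* **`strict_handbook` flag.** A comment naming only a "random number
  generator", with no computer/software mention, does not strictly confirm
  an electronic process. The default taxonomy keeps the category in the
  computer parent (expected low) — the convention behind the headline
  numbers; the flag reassigns it to method-not-described, which moves
  overall discordance from 12% to 13% and low-judged discordance from 20% to
  22% at the reference distribution (98 such trials, all judged low).
* **Negation is not modelled.** "No computer was used" matches the computer
  rule. The trigger vocabulary is affirmative-method phrasing; negated
  method statements are rare in RoB supports and handling them would require
  scope resolution the rule format cannot honestly express. This is the main
  known limitation of the classifier on free text.
* Matching is case-insensitive on whitespace-normalised text with
  word-boundary-anchored patterns and built-in -is-/-iz- spelling variants.

## Exclusion rules

Exclusion is per study, first matching rule wins, so the accounting is
mutually exclusive: (1) missing RoB table or duplicated entry (from reader
warnings or repeated domain rows; in the flat interchange format a row with
an empty `domain` field marks a table-less study); (2) sequence-generation
domain missing — the domain matcher accepts any label containing "random
sequence generation", or "sequence generation" without "allocation", since
real reviews vary in wording; (3) customised judgment (anything that does
not normalise to low/unclear/high, e.g. "moderate"); (4) empty support or a
placeholder from the closed set {"n/a", "na", "not applicable"} (additional
placeholders are opt-in, never heuristic). Studies excluded for no
detectable reason cannot be reproduced mechanically; the `UNEXPLAINED`
reason exists in the data model but is never auto-assigned. Reviews that
lose every study are counted as excluded reviews; review-level exclusion is
derived, not separately ruled.

## Synthetic corpus generator

The generator emulates the *output structure* of a real audited corpus — the
joint category x judgment distribution and the exclusion pathologies — not
the linguistics of real comments. Defaults are the reference audit's
conditions: 10,103 analysable trials in 704 reviews distributed per the
published 57-cell table, plus 187 pathological records (19 customised
judgments, 96 missing domains, 16 missing RoB tables, 56 empty/"N/A"
supports) placed in 14 dedicated reviews so review-level accounting
reproduces 718 seen / 14 dropped / 704 analysed.

* **Exact-allocation mode** apportions cell counts by largest remainder
  (ties to earlier canonical cell order); at the default configuration the
  quotas are integral, so the reference table is reproduced cell for cell,
  and the rule matters only for scaled-down corpora.
* **Multinomial mode** draws the cell vector once from a seeded multinomial
  for stochastic tests; realised cells sit within 4 binomial standard errors
  of expectation.
* Support texts cycle deterministically through ≥3 templates per category;
  the templates live in the same YAML document as the rules and are
  validated to round-trip through the classifier (zero misroutes), which is
  what makes the end-to-end reproduction exact rather than approximate.
* One seeded stream, fixed draw order (cell counts; templates and pathology
  placement are deterministic), so a config + seed pins the output files
  byte for byte.
* Trials are dealt to reviews round-robin; the per-review study-count
  distribution of real corpora is unknown and not emulated (noted in the
  manifest).

Consequently, passing end-to-end tests demonstrate that the pipeline's
bookkeeping, classification of the template vocabulary, and all derived
arithmetic are correct; they do not demonstrate classifier recall on the
full variety of real reviewer prose, which has no public gold standard.

## Numerical conventions

Percentages are plain frequencies (no inferential statistics, matching the
descriptive design). Two roundings are carried everywhere: one-decimal
(table style, e.g. 99.2) and nearest-integer (prose style, e.g. 28), because
audit reports conventionally mix both. Percentages of empty groups are
`None`/NA, never 0. Output column order is Total, High, Unclear, Low.
Cross-tabulations are validated for conservation (cells sum to n; parent
totals sum to member totals; the per-judgment and per-parent discordance
aggregations must agree) before any summary is reported.

## Problem sizes

The default test and acceptance runs use the reference-scale corpus
(10,103 + 187 records, ~1 s end-to-end), 100 random corpora of n = 1,000
for the summariser-vs-naive-loop equivalence check, and n = 10,000 for the
multinomial calibration check; these sizes make every reference figure
reproducible exactly while keeping the whole suite fast.
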
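# robaudit

Audit Cochrane risk-of-bias (RoB) judgments for **random sequence generation**
against Cochrane Handbook guidance.

## The problem

Cochrane systematic reviews appraise every included randomised trial with the
RoB tool: for each bias domain the review authors record a judgment (low /
unclear / high risk) and a free-text *support for judgement* comment that is
supposed to justify it. The Handbook (Table 8.5.d) is explicit about which
described randomisation methods warrant which judgment — a random number
table, computer generation, coin tossing etc. warrant *low* risk;
quasi-random rules (alternation, birth dates, record numbers) warrant *high*
risk; and a comment that never describes the method warrants *unclear* risk.
In practice authors often depart from this guidance, e.g. judging a trial
*low* risk when the comment only says "block randomisation" or "central
randomisation", which describes no random sequence at all.

`robaudit` turns that audit into a reproducible pipeline for
meta-epidemiologists and evidence-synthesis methodologists:

1. **ingest** — read RoB tables from a flat interchange format (CSV/JSONL) or
   an HTML fixture dialect mirroring a review's "Characteristics of included
   studies" page; normalise judgments; apply the exclusion rules
   (customised judgments, missing domains or RoB tables, empty/"N/A"
   supports, duplicates) with full accounting.
2. **classify** — assign each support comment to exactly one of **19
   categories** via tiered, first-match-wins keyword rules with a complete
   rule trace. The categories group into **5 parent categories**, each
   carrying one Handbook-expected judgment:

   | Parent category | Expected judgment |
   |---|---|
   | Random number table | low |
   | Computer / software / internet (incl. IVRS, minimisation, web-based) | low |
   | Mechanical (coin, lots, cards/envelopes, dice) | low |
   | Incomplete or inappropriate (quasi-random, erroneous, preference) | high |
   | Method not described (incl. blocks-only, envelopes-only, central-only, baseline (im)balance) | unclear |

3. **concordance** — a judgment is *discordant* (inadequate) when it differs
   from its comment's expected judgment. The module builds the 19 x 3
   category-by-judgment cross-tabulation and derives overall, per-judgment,
   per-parent and per-category discordance, with table-style (one decimal)
   and prose-style (integer) percent roundings.
4. **synthetic** — a seeded corpus generator with a configurable joint
   category x judgment distribution (exact largest-remainder allocation or
   multinomial sampling) plus configurable excluded-record pathologies, so
   the whole pipeline runs and is tested fully offline.

## Worked example

```python
import robaudit as ra

# generate a corpus at the reference conditions: 10,103 analysable trials in
# 704 reviews with the published joint distribution, plus 187 pathological
# records in 14 dedicated reviews
entries, manifest = ra.generate_entries(ra.default_config(seed=1))
result = ra.run_audit(entries)

c = result.corpus
print(c.n_studies_seen, c.n_included, c.n_excluded)   # 10290 10103 187
ov = result.summary.overall
print(ov.total, ov.discordant, ov.percent_int)        # 10103 1220 12
```

One judgment in eight departs from Handbook guidance. Discordance
concentrates in *high* judgments (101/365 = 28%), then *low* (983/4,951 =
20%), then *unclear* (136/4,787 = 3%); the most common single error is
judging *low* risk when the method was never described (974 trials, e.g.
123/124 = 99.2% of central-randomisation-only comments judged low).

The same summary can be computed straight from a published 19 x 3 table,
without row-level data:

```python
from robaudit.reference import REFERENCE_CELL_COUNTS
s = ra.summarize_from_counts(REFERENCE_CELL_COUNTS)
print(s.overall.discordant, s.overall.percent_int)    # 1220 12

# sensitivity: treat a bare "random number generator" (no computer
# mentioned) as method-not-described instead of an adequate method
s = ra.summarize_from_counts(REFERENCE_CELL_COUNTS, strict_handbook=True)
print(s.overall.percent_int)                          # 13
```

### Command line

```sh
robaudit simulate --n 10103 --seed 1 --out corpus/       # synthetic corpus
robaudit audit --in corpus/corpus.csv --out run/         # full audit
# n=10103  discordant=1220 (12%)  excluded=187
robaudit table2 --counts counts.csv                      # render a 19x3 table
robaudit export-rules --out rules.yaml                   # inspect/edit rules
```

`audit` writes `exclusions.csv`, `classified.csv` (with per-trial category,
expected judgment and matched pattern), `table.txt` (the cross-tabulation
with row percentages) and `summary.json`.

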
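"""Cross-tabulation and discordance summaries."""

import numpy as np
import pytest

from robaudit.classifier import ClassifiedTrial
from robaudit.concordance import (
    CrossTab,
    GroupStat,
    assess,
    build_crosstab,
    render_table,
    summarize,
    summarize_from_counts,
)
from robaudit.taxonomy import CategoryId, Judgment, build_taxonomy

from conftest import make_entry


def _trial(category, observed, taxonomy, study="S1"):
    parent = taxonomy.parent_of(category)
    return ClassifiedTrial(
        entry=make_entry(study=study, judgment=observed.value.title() + " risk"),
        category=category,
        parent=parent,
        expected=taxonomy.expected_of(parent),
        observed=observed,
    )


def _random_trials(rng, n, taxonomy):
    cats = list(CategoryId)
    judgs = list(Judgment)
    return [
        _trial(cats[rng.integers(len(cats))], judgs[rng.integers(len(judgs))],
               taxonomy, study=f"S{i}")
        for i in range(n)
    ]


# ------------------------------------------------------------------- assess

@pytest.mark.parametrize(
    "category, observed, concordant",
    [
        (CategoryId.QUASI_RANDOM, Judgment.HIGH, True),
        (CategoryId.NOT_DESCRIBED, Judgment.LOW, False),
        (CategoryId.COIN_TOSSING, Judgment.LOW, True),
        (CategoryId.CENTRAL_RANDOMISATION_NO_METHOD, Judgment.LOW, False),
    ],
)
def test_assess_sets_concordance_flag(category, observed, concordant, taxonomy):
    (t,) = assess([_trial(category, observed, taxonomy)])
    assert t.concordant is concordant
    assert t.concordant == (t.observed == t.expected)


def test_assess_is_pure_and_order_preserving(taxonomy):
    trials = [
        _trial(CategoryId.IVRS, Judgment.LOW, taxonomy, "S1"),
        _trial(CategoryId.IVRS, Judgment.HIGH, taxonomy, "S2"),
    ]
    out1, out2 = assess(trials), assess(trials)
    assert [t.entry.study_id for t in out1] == ["S1", "S2"]
    assert out1 == out2
    assert all(t.concordant is None for t in trials)  # inputs untouched


# ------------------------------------------------------------------- crosstab

def test_empty_crosstab_is_all_zero():
    ct = build_crosstab([])
    assert ct.n == 0
    assert all(v == 0 for v in ct.cells.values())
    assert ct.row_percent(CategoryId.IVRS, Judgment.LOW) is None


def test_two_trials_in_same_cell(taxonomy):
    trials = [
        _trial(CategoryId.MINIMISATION, Judgment.LOW, taxonomy, s) for s in ("S1", "S2")
    ]
    ct = build_crosstab(trials)
    assert ct.cell(CategoryId.MINIMISATION, Judgment.LOW) == 2
    assert ct.n == 2
    assert sum(ct.cells.values()) == 2


def test_crosstab_conservation_invariants(taxonomy):
    rng = np.random.default_rng(11)
    ct = build_crosstab(_random_trials(rng, 500, taxonomy))
    assert sum(ct.judgment_total(j) for j in Judgment) == ct.n == 500
    for p in taxonomy.parents:
        assert ct.parent_total(p, taxonomy) == sum(
            ct.category_total(c) for c in taxonomy.members_of(p)
        )
    ct.validate(taxonomy)


def test_crosstab_dataframe_shape():
    df = build_crosstab([]).to_dataframe()
    assert df.shape == (19, 4)
    assert list(df.columns) == ["Total", "High", "Unclear", "Low"]


# ------------------------------------------------------------------- summaries

def test_summarize_equals_per_trial_loop_oracle(taxonomy):
    rng = np.random.default_rng(7)
    for _ in range(20):
        trials = _random_trials(rng, 1000, taxonomy)
        summary = summarize(build_crosstab(trials), taxonomy)
        # independent oracle: naive loop over trials
        naive = sum(1 for t in trials if t.observed != taxonomy.expected_judgment(t.category))
        assert summary.overall.discordant == naive
        for j in Judgment:
            naive_j = sum(
                1 for t in trials
                if t.observed == j and taxonomy.expected_judgment(t.category) != j
            )
            assert summary.per_judgment[j].discordant == naive_j


def test_summaries_are_additive_over_review_partition(taxonomy):
    rng = np.random.default_rng(19)
    trials = _random_trials(rng, 600, taxonomy)
    whole = summarize(build_crosstab(trials), taxonomy)
    thirds = [trials[i::3] for i in range(3)]
    parts = [summarize(build_crosstab(p), taxonomy) for p in thirds]
    assert sum(p.overall.discordant for p in parts) == whole.overall.discordant
    assert sum(p.n for p in parts) == whole.n


def test_one_extra_discordant_trial_increments_count_by_one(taxonomy):
    rng = np.random.default_rng(23)
    trials = _random_trials(rng, 100, taxonomy)
    base = summarize(build_crosstab(trials), taxonomy)
    extra = _trial(CategoryId.NOT_DESCRIBED, Judgment.LOW, taxonomy, "SX")
    bumped = summarize(build_crosstab(trials + [extra]), taxonomy)
    assert bumped.overall.discordant == base.overall.discordant + 1


def test_all_concordant_toy_crosstab_is_zero_discordant(taxonomy):
    trials = [
        _trial(c, taxonomy.expected_judgment(c), taxonomy, f"S{i}")
        for i, c in enumerate(CategoryId)
    ]
    summary = summarize(build_crosstab(trials), taxonomy)
    assert summary.overall.discordant == 0
    assert summary.overall.percent_int == 0


def test_summarize_from_counts_uniform_one_per_cell(taxonomy):
    cells = {(c, j): 1 for c in CategoryId for j in Judgment}
    summary = summarize_from_counts(cells)
    # brute-force enumeration over the 57 cells
    expected_discordant = sum(
        1 for c in CategoryId for j in Judgment if taxonomy.expected_judgment(c) != j
    )
    assert summary.n == 57
    assert summary.overall.discordant == expected_discordant


def test_summarize_from_counts_single_cell_concordant():
    cells = {(c, j): 0 for c in CategoryId for j in Judgment}
    cells[(CategoryId.NOT_DESCRIBED, Judgment.UNCLEAR)] = 5
    summary = summarize_from_counts(cells)
    assert summary.n == 5
    assert summary.overall.discordant == 0
    # empty groups report undefined percent, never 0
    assert summary.per_category[CategoryId.IVRS].percent is None


def test_summarize_from_counts_matches_trial_route(taxonomy):
    rng = np.random.default_rng(31)
    trials = _random_trials(rng, 400, taxonomy)
    ct = build_crosstab(trials)
    via_counts = summarize_from_counts(dict(ct.cells))
    via_trials = summarize(ct, taxonomy)
    assert via_counts.to_dict() == via_trials.to_dict()


def test_negative_count_rejected():
    cells = {(c, j): 0 for c in CategoryId for j in Judgment}
    cells[(CategoryId.IVRS, Judgment.LOW)] = -1
    with pytest.raises(ValueError, match="negative"):
        summarize_from_counts(cells)


def test_percent_roundings_both_styles():
    s = GroupStat(total=365, discordant=101)
    assert s.percent_1dp == 27.7
    assert s.percent_int == 28
    assert GroupStat(total=0, discordant=0).percent is None


# ------------------------------------------------------------------- rendering

def test_render_table_zero_counts_has_na_percents():
    text = render_table(build_crosstab([]))
    assert "NA" in text
    assert "Total" in text


def test_render_table_layout_row_order(taxonomy):
    rng = np.random.default_rng(5)
    text = render_table(build_crosstab(_random_trials(rng, 200, taxonomy)))
    lines = text.splitlines()
    assert lines[0].startswith("Category")
    assert "High, N (%)" in lines[0] and lines[0].index("High") < lines[0].index("Low")
    parents = [i for i, l in enumerate(lines) if "risk)" in l]
    assert len(parents) == 5
    assert lines[-1].startswith("Total")
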
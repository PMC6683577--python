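"""Interchange/HTML readers, judgment normalisation and exclusion rules."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from robaudit.ingest import (
    FormatError,
    IngestWarning,
    ParseError,
    apply_exclusions,
    is_sequence_generation_domain,
    normalize_judgment,
    parse_rob_fixture_html,
    read_interchange,
    write_interchange,
)
from robaudit.synthetic import default_config, generate_entries, write_fixture_html
from robaudit.taxonomy import Judgment

from conftest import SEQ_DOMAIN, make_entry


# ---------------------------------------------------------------- normalisation

@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Low risk", Judgment.LOW),
        ("low", Judgment.LOW),
        ("UNCLEAR RISK", Judgment.UNCLEAR),
        ("High risk of bias", Judgment.HIGH),
        ("  high  ", Judgment.HIGH),
        ("moderate", None),
        ("Some concerns", None),
        ("", None),
        ("lowish", None),
    ],
)
def test_judgment_normalisation(raw, expected):
    assert normalize_judgment(raw) is expected


@pytest.mark.parametrize(
    "domain, matches",
    [
        ("Random sequence generation (selection bias)", True),
        ("RANDOM SEQUENCE GENERATION", True),
        ("Sequence generation", True),
        ("Sequence generation / allocation concealment", False),
        ("Allocation concealment (selection bias)", False),
        ("Blinding of participants", False),
    ],
)
def test_sequence_generation_domain_matcher(domain, matches):
    assert is_sequence_generation_domain(domain) is matches


# ---------------------------------------------------------------- interchange

CSV_HEADER = "review_id,study_id,domain,judgment,support\n"


def test_read_csv_normalises_judgment():
    src = io.StringIO(
        CSV_HEADER + f'R1,S1,"{SEQ_DOMAIN}",Low risk,computer generated\n'
    )
    (entry,) = read_interchange(src, dialect="csv")
    assert entry.judgment is Judgment.LOW
    assert entry.judgment_raw == "Low risk"
    assert entry.support_text == "computer generated"


def test_read_csv_keeps_customised_judgment_raw():
    src = io.StringIO(CSV_HEADER + f'R1,S1,"{SEQ_DOMAIN}",moderate,whatever\n')
    (entry,) = read_interchange(src, dialect="csv")
    assert entry.judgment is None
    assert entry.judgment_raw == "moderate"


def test_read_csv_empty_stream_with_header():
    assert read_interchange(io.StringIO(CSV_HEADER), dialect="csv") == []


def test_read_csv_missing_column_names_it():
    with pytest.raises(FormatError, match="support"):
        read_interchange(io.StringIO("review_id,study_id,domain,judgment\n"), dialect="csv")


def test_read_undecodable_bytes_reports_offset(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_bytes(CSV_HEADER.encode() + b"R1,S1,d,\xff\xfe,low,x\n")
    with pytest.raises(FormatError, match="byte offset"):
        read_interchange(p, dialect="csv")


def test_read_jsonl_and_bad_line():
    good = '{"review_id":"R1","study_id":"S1","domain":"%s","judgment":"high","support":"alternation"}\n' % SEQ_DOMAIN
    (entry,) = read_interchange(io.StringIO(good), dialect="jsonl")
    assert entry.judgment is Judgment.HIGH
    with pytest.raises(FormatError, match="line 1"):
        read_interchange(io.StringIO("{not json}\n"), dialect="jsonl")


@pytest.mark.parametrize("dialect", ["csv", "jsonl"])
def test_interchange_round_trip_is_content_identical(dialect):
    entries = [
        make_entry(study=f"S{i}", judgment=j, support=s, design=d)
        for i, (j, s, d) in enumerate([
            ("Low risk", "computer generated", "RCT"),
            ("moderate", "quote with, comma and \"quotes\"", None),
            ("Unclear risk", "not stated", "NRS"),
        ])
    ]
    buf = io.StringIO()
    write_interchange(entries, buf, dialect=dialect)
    buf.seek(0)
    assert read_interchange(buf, dialect=dialect) == entries


# ---------------------------------------------------------------- HTML fixture

def _fixture_html(n_studies=2, n_domains=7):
    entries = []
    domains = [SEQ_DOMAIN] + [f"Other domain {k}" for k in range(1, n_domains)]
    for i in range(n_studies):
        for d in domains:
            entries.append(make_entry(study=f"S{i+1}", domain=d, support="not stated",
                                      judgment="Unclear risk"))
    buf = io.StringIO()
    write_fixture_html(entries, buf)
    return buf.getvalue()


def test_fixture_parse_complete_document():
    entries, warnings = parse_rob_fixture_html(_fixture_html(2, 7))
    assert len(entries) == 14
    assert warnings == []
    assert {e.study_id for e in entries} == {"S1", "S2"}


def test_fixture_study_without_rob_table_yields_warning():
    rows = [
        make_entry(study="S1", support="not stated", judgment="Unclear risk"),
        make_entry(study="S2", domain="", judgment="", support=""),  # no RoB table
        make_entry(study="S3", support="not stated", judgment="Unclear risk"),
    ]
    buf = io.StringIO()
    write_fixture_html(rows, buf)
    entries, warnings = parse_rob_fixture_html(buf.getvalue())
    assert {e.study_id for e in entries} == {"S1", "S3"}
    assert [(w.kind, w.study_id) for w in warnings] == [("ROB_TABLE_MISSING", "S2")]


def test_fixture_duplicated_study_section_flagged():
    row = make_entry(study="S1", support="not stated", judgment="Unclear risk")
    buf = io.StringIO()
    write_fixture_html([row, row], buf)
    entries, warnings = parse_rob_fixture_html(buf.getvalue())
    assert len(entries) == 1
    assert [(w.kind, w.study_id) for w in warnings] == [("DUPLICATE_ENTRY", "S1")]


def test_fixture_markup_without_studies_is_parse_error():
    with pytest.raises(ParseError):
        parse_rob_fixture_html("<html><body><p>nothing here</p></body></html>")


# ---------------------------------------------------------------- exclusions

def test_customised_judgment_excluded():
    corpus = apply_exclusions([make_entry(judgment="moderate")])
    assert corpus.included == []
    assert [r.reason for r in corpus.exclusions] == ["CUSTOMISED_JUDGMENT"]


@pytest.mark.parametrize("support", ["", "  ", "N/A", "n/a", "NA", "Not applicable", "n/a."])
def test_na_supports_excluded(support):
    corpus = apply_exclusions([make_entry(support=support)])
    assert [r.reason for r in corpus.exclusions] == ["EMPTY_SUPPORT"]


def test_unusual_placeholders_off_by_default_configurable():
    assert apply_exclusions([make_entry(support="—")]).included
    corpus = apply_exclusions([make_entry(support="—")], extra_na_placeholders=["—"])
    assert [r.reason for r in corpus.exclusions] == ["EMPTY_SUPPORT"]


def test_domain_missing_excluded_with_design_annotation():
    corpus = apply_exclusions([
        make_entry(domain="Allocation concealment (selection bias)", design="NRS")
    ])
    (rec,) = corpus.exclusions
    assert rec.reason == "DOMAIN_MISSING"
    assert rec.study_design == "NRS"


def test_rob_table_missing_via_placeholder_row_and_warning():
    corpus = apply_exclusions([make_entry(domain="", judgment="", support="")])
    assert [r.reason for r in corpus.exclusions] == ["ROB_TABLE_MISSING"]
    corpus = apply_exclusions(
        [], warnings=[IngestWarning("ROB_TABLE_MISSING", "R1", "S9", "")]
    )
    assert [(r.reason, r.study_id) for r in corpus.exclusions] == [("ROB_TABLE_MISSING", "S9")]


def test_duplicate_rows_excluded_once():
    row = make_entry()
    corpus = apply_exclusions([row, row])
    assert [r.reason for r in corpus.exclusions] == ["DUPLICATE_ENTRY"]
    assert corpus.n_studies_seen == 1


def test_rule_order_warning_beats_customised_judgment():
    # a study flagged duplicate also has a customised judgment: first rule wins
    row = make_entry(judgment="moderate")
    corpus = apply_exclusions([row], warnings=[IngestWarning("DUPLICATE_ENTRY", "R1", "S1", "")])
    assert [r.reason for r in corpus.exclusions] == ["DUPLICATE_ENTRY"]


def test_complete_entry_included_with_passthrough():
    rows = [
        make_entry(),
        make_entry(domain="Blinding of participants", judgment="High risk", support="open label"),
    ]
    corpus = apply_exclusions(rows)
    assert len(corpus.included) == 1
    assert corpus.included[0].is_sequence_generation
    assert len(corpus.passthrough) == 1
    assert corpus.exclusions == []


def test_exclusion_is_idempotent():
    entries, _ = generate_entries(default_config(seed=3))
    corpus = apply_exclusions(entries)
    again = apply_exclusions(corpus.included)
    assert again.n_excluded == 0
    assert again.included == corpus.included


def test_declared_study_count_mismatch_warns_never_drops():
    corpus = apply_exclusions([make_entry()], declared_study_counts={"R1": 3})
    assert corpus.n_included == 1
    kinds = [w.kind for w in corpus.warnings]
    assert "STUDY_COUNT_MISMATCH" in kinds


@settings(derandomize=True, max_examples=40)
@given(
    studies=st.lists(
        st.tuples(
            st.sampled_from(["ok", "custom", "empty", "nodomain", "notable"]),
            st.integers(0, 4),
        ),
        min_size=0,
        max_size=25,
    )
)
def test_conservation_included_plus_excluded_equals_seen(studies):
    entries = []
    for i, (kind, rev) in enumerate(studies):
        kw = dict(review=f"R{rev}", study=f"S{i}")
        if kind == "ok":
            entries.append(make_entry(**kw))
        elif kind == "custom":
            entries.append(make_entry(judgment="moderate", **kw))
        elif kind == "empty":
            entries.append(make_entry(support="N/A", **kw))
        elif kind == "nodomain":
            entries.append(make_entry(domain="Other bias", **kw))
        else:
            entries.append(make_entry(domain="", judgment="", support="", **kw))
    corpus = apply_exclusions(entries)
    assert corpus.n_included + corpus.n_excluded == len(studies)
    assert corpus.n_reviews_included + corpus.n_reviews_excluded == corpus.n_reviews_seen
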
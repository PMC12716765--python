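"""Parsing, deduplication and case assembly."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from faers_signals.faers_io import (
    Dialect,
    FaersIOError,
    PartialDate,
    ReportKey,
    assemble_cases,
    classify_table,
    convert_age,
    convert_weight,
    deduplicate,
    read_bundle,
)

from _oracles import dedup_oracle
from conftest import write_tiny_bundle


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_read_bundle_parses_wellformed_rows(tmp_path):
    paths = write_tiny_bundle(tmp_path, demo_rows=[
        "11$1$20230101$20221231$50$YR$F$70$KG$MD$US$US",
        "21$2$20230102$$$$M$$$CN$FR$FR",
        "31$3$20230103$20221201$60$YR$$$$$$",
    ])
    bundle = read_bundle(paths)
    assert len(bundle.rows("DEMO")) == 3
    assert not bundle.rejects


def test_malformed_line_is_rejected_not_dropped(tmp_path):
    paths = write_tiny_bundle(tmp_path, demo_rows=[
        "11$1$20230101$$$$F$$$$$",
        "21$2$20230102",  # wrong field count
    ])
    bundle = read_bundle(paths)
    assert len(bundle.rows("DEMO")) == 1
    assert len(bundle.rejects) == 1
    assert "expected 12 fields" in bundle.rejects[0].reason


def test_orphan_detail_rows_are_quarantined(tmp_path):
    paths = write_tiny_bundle(
        tmp_path,
        demo_rows=["11$1$20230101$$$$F$$$$$"],
        reac_rows=["11$1$NAUSEA", "99$9$HEADACHE"],
    )
    bundle = read_bundle(paths)
    assert len(bundle.rows("REAC")) == 1
    assert any("orphan" in r.reason for r in bundle.rejects)


def test_unreadable_file_is_fatal(tmp_path):
    with pytest.raises(FaersIOError, match="unreadable"):
        read_bundle([tmp_path / "DEMO_missing.txt"])


def test_unclassifiable_table_name_is_fatal(tmp_path):
    p = tmp_path / "MYSTERY.txt"
    p.write_text("a$b\n1$2\n")
    with pytest.raises(FaersIOError, match="classify"):
        read_bundle([p])


@pytest.mark.parametrize("fname,expected", [
    ("DEMO12Q3.TXT", "DEMO"),
    ("drug_2020q1.txt", "DRUG"),
    ("reac_synth.txt", "REAC"),
])
def test_classify_table_by_name_pattern(fname, expected):
    assert classify_table(fname) == expected


# ---------------------------------------------------------------------------
# partial dates
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("text,expect", [
    ("20230115", ("day", 2023, 1, 15)),
    ("202301", ("month", 2023, 1, None)),
    ("2023", ("year", 2023, None, None)),
    ("20231340", None),  # invalid month
    ("", None),
    ("abc", None),
])
def test_partial_date_parsing(text, expect):
    d = PartialDate.parse(text)
    if expect is None:
        assert d is None
    else:
        prec, y, m, day = expect
        assert (d.precision, d.year, d.month, d.day) == (prec, y, m, day)


def test_partial_date_orders_by_earliest_completion():
    assert PartialDate.parse("2023") < PartialDate.parse("202302")
    assert PartialDate.parse("202301") < PartialDate.parse("20230102")
    assert str(PartialDate.parse("20230102")) == "20230102"


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------


def _key(caseid, fda, pid):
    return ReportKey(pid, caseid, PartialDate.parse(str(fda)))


def test_dedup_singleton_passthrough():
    keys = [_key(100, 20230101, 1001)]
    assert deduplicate(keys) == keys


def test_dedup_keeps_latest_fda_dt():
    keys = [_key(100, 20230101, 1001), _key(100, 20230301, 1002)]
    assert [k.primaryid for k in deduplicate(keys)] == [1002]


def test_dedup_ties_break_by_highest_primaryid():
    keys = [_key(100, 20230301, 1002), _key(100, 20230301, 1000)]
    assert [k.primaryid for k in deduplicate(keys)] == [1002]


def test_dedup_empty_input():
    assert deduplicate([]) == []


key_strategy = st.builds(
    _key,
    st.integers(1, 20),
    st.sampled_from([20230101, 20230102, 20230301, 202302, 2023]),
    st.integers(1, 10_000),
)


@settings(max_examples=200, deadline=None)
@given(st.lists(key_strategy, max_size=40))
def test_dedup_matches_bruteforce_oracle_and_is_idempotent(keys):
    result = deduplicate(keys)
    assert result == dedup_oracle(keys)
    assert deduplicate(result) == result
    assert len(result) <= len(keys)
    caseids = [k.caseid for k in result]
    assert caseids == sorted(set(k.caseid for k in keys))


# ---------------------------------------------------------------------------
# unit conversion and assembly
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("value,unit,expected", [
    ("5", "DEC", 50.0),
    ("50", "YR", 50.0),
    ("24", "MON", 2.0),
    ("730.5", "DY", 2.0),
    ("17532", "HR", 2.0),
    ("200", "YR", None),   # implausible -> missing
    ("50", "XX", None),    # unmappable unit
    ("", "YR", None),
])
def test_age_conversion(value, unit, expected):
    got = convert_age(value, unit)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected)


def test_weight_conversion_lbs_to_kg():
    assert convert_weight("154", "LBS") == pytest.approx(154 * 0.453592)
    assert convert_weight("70", "KG") == 70.0
    assert convert_weight("-5", "KG") is None


def test_assemble_aggregates_and_deduplicates(tmp_path):
    paths = write_tiny_bundle(
        tmp_path,
        demo_rows=[
            # caseid 1 has two versions; the 20230301 one must win
            "11$1$20230101$20221231$5$DEC$F$154$LBS$MD$US$US",
            "12$1$20230301$20221231$5$DEC$F$154$LBS$MD$US$US",
            "21$2$20230102$$$$M$$$CN$$FR",
        ],
        drug_rows=["12$1$1$PS$MIRTAZAPINE", "21$2$1$PS$ASPIRIN "],
        reac_rows=["12$1$NAUSEA", "12$1$NAUSEA", "12$1$Coma", "21$2$ "],
        ther_rows=["12$1$1$20221101$"],
        outc_rows=["12$1$HO", "12$1$DE"],
    )
    cases = assemble_cases([read_bundle(paths)])
    assert len(cases) == 2
    c1 = cases[0]
    assert c1.key.primaryid == 12
    assert c1.age_years == 50.0                       # DEC code
    assert c1.weight_kg == pytest.approx(69.85, abs=0.01)  # 154 lbs -> 69.853 kg
    assert c1.reactions == {"NAUSEA", "COMA"}         # set semantics
    assert c1.outcomes == {"HO", "DE"}
    assert c1.drugs[0].name == "MIRTAZAPINE"
    assert str(c1.drugs[0].start_date) == "20221101"
    c2 = cases[1]
    assert c2.reactions == frozenset()                # empty PT dropped
    assert c2.country == "FR"                         # reporter-country fallback
    assert c2.drugs[0].name == "ASPIRIN"


def test_round_trip_synthetic_bundle(small_sim_files):
    """Write -> read -> assemble recovers every planted case field-for-field."""
    cfg, bundle, truth, table_paths = small_sim_files
    read_back = read_bundle(table_paths)
    for name in ("DEMO", "DRUG", "REAC", "THER", "OUTC"):
        assert len(read_back.rows(name)) == len(bundle.rows(name))
    assert not read_back.rejects
    cases = assemble_cases([read_back])
    assert len(cases) == cfg.n_cases
    by_caseid = {c.key.caseid: c for c in cases}
    for want in truth.cases:
        got = by_caseid[want.key.caseid]
        assert got.key == want.key
        assert got.sex == want.sex
        assert got.reactions == want.reactions
        assert got.outcomes == want.outcomes
        assert got.country == want.country
        assert got.reporter_occupation == want.reporter_occupation
        assert got.drugs == want.drugs
        assert got.event_date == want.event_date
        if want.age_years is None:
            assert got.age_years is None
        else:
            assert got.age_years == pytest.approx(want.age_years)
        if want.weight_kg is None:
            assert got.weight_kg is None
        else:
            assert got.weight_kg == pytest.approx(want.weight_kg)


def test_custom_delimiter_dialect(tmp_path):
    p = tmp_path / "DEMO_tab.txt"
    p.write_text("primaryid\tcaseid\tfda_dt\n11\t1\t20230101\n")
    bundle = read_bundle([p], Dialect("\t"))
    assert len(bundle.rows("DEMO")) == 1
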
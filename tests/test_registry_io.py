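"""Readers, age harmonization, multiple-cause parsing and population tables."""

import csv
import warnings

import pytest
from hypothesis import given, strategies as st

from sepsisburden.registry_io import (
    AGE_GROUPS,
    PopulationTable,
    RegistryError,
    SchemaConfig,
    build_standard,
    harmonize_age,
    parse_mcod_lines,
    read_population,
    read_single_cause_table,
    read_mcod_table,
    write_single_cause_table,
)

from conftest import make_record, uniform_population


# ---------------------------------------------------------------------------
# age harmonization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "unit, value, years, group",
    [
        ("months", 6, 0.5, "<1"),
        ("years", 0, 0.0, "<1"),
        ("years", 1, 1.0, "1-19"),
        ("years", 19, 19.0, "1-19"),
        ("years", 20, 20.0, "20-39"),
        ("years", 59.9, 59.9, "40-59"),
        ("years", 60, 60.0, "60+"),   # sixty-year-olds are in the open top bin
        ("years", 101, 101.0, "60+"),
        ("days", 30, 30 / 365.25, "<1"),
        ("hours", 12, 12 / 8766, "<1"),
    ],
)
def test_harmonize_age(unit, value, years, group):
    got_years, got_group = harmonize_age(unit, value)
    assert got_years == pytest.approx(years)
    assert got_group == group


def test_harmonize_age_rejects_bad_inputs():
    with pytest.raises(RegistryError):
        harmonize_age("years", -1)
    with pytest.raises(RegistryError):
        harmonize_age("fortnights", 2)


@given(st.floats(min_value=0, max_value=120, allow_nan=False))
def test_age_group_is_the_unique_containing_bin(age):
    _, group = harmonize_age("years", age)
    edges = {"<1": (0, 1), "1-19": (1, 20), "20-39": (20, 40), "40-59": (40, 60), "60+": (60, 1e9)}
    lo, hi = edges[group]
    assert lo <= age < hi


# ---------------------------------------------------------------------------
# single-cause reader
# ---------------------------------------------------------------------------

def _write_rows(path, rows, schema=None):
    schema = schema or SchemaConfig()
    header = ["ANO", "SEXO", "EDAD_TIPO", "EDAD_CANT", "REGION", "COMUNA", "DIAG1", "COND_EGRESO"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=schema.delimiter)
        writer.writerow(header)
        writer.writerows(rows)


GOOD = ["2023", "1", "1", "64", "R01", "01101", "A419", "1"]


def test_reader_count_conservation(tmp_path):
    rows = [list(GOOD) for _ in range(10)]
    rows[3][6] = "41A0"  # illegal code
    path = tmp_path / "d.csv"
    _write_rows(path, rows)
    records, rejects = read_single_cause_table(path, event_kind="death")
    assert len(records) == 9
    assert len(rejects) == 1
    assert rejects[0].reason.startswith("bad-icd10")
    assert len(records) + len(rejects) == 10


def test_discharge_reader_drops_death_outcomes(tmp_path):
    rows = [list(GOOD) for _ in range(4)]
    rows[2][7] = "2"  # in-hospital death
    path = tmp_path / "d.csv"
    _write_rows(path, rows)
    records, rejects = read_single_cause_table(path, event_kind="discharge_alive")
    assert len(records) == 3
    assert [r.reason for r in rejects] == ["outcome-not-alive"]
    # the death reader keeps the same row
    records, _ = read_single_cause_table(path, event_kind="death")
    assert len(records) == 4


def test_sentinel_geography_rejected(tmp_path):
    rows = [list(GOOD), list(GOOD)]
    rows[1][5] = "99999"
    path = tmp_path / "d.csv"
    _write_rows(path, rows)
    records, rejects = read_single_cause_table(path)
    assert len(records) == 1
    assert rejects[0].reason == "sentinel-geography"


def test_empty_file_warns(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        records, rejects = read_single_cause_table(path)
    assert records == [] and rejects == []
    assert caught


def test_round_trip_preserves_records(tmp_path):
    records = [
        make_record(age_years=0.5, age_group="<1"),
        make_record(cause="J18", age_years=19.0, age_group="1-19", sex="male"),
        make_record(cause="N390", event_kind="discharge_alive", age_years=83.0),
        make_record(comuna="03102", region="R03", year=2021),
    ]
    # deaths and live discharges live in separate tables, as in the source
    reread = []
    for kind in ("death", "discharge_alive"):
        path = tmp_path / f"rt_{kind}.csv"
        subset = [r for r in records if r.event_kind == kind]
        write_single_cause_table(subset, path)
        got, rejects = read_single_cause_table(path, event_kind=kind)
        assert rejects == []
        assert len(got) == len(subset)  # count conservation
        reread.extend(got)
    assert sorted(reread, key=repr) == sorted(records, key=repr)


# ---------------------------------------------------------------------------
# multiple-cause parsing
# ---------------------------------------------------------------------------

def test_parse_mcod_lines_examples():
    assert parse_mcod_lines("*A419*", "*J960*I10X*", "", "") == ["A419", "J960", "I10"]
    assert parse_mcod_lines("", "", "", "") == []
    # duplicates preserved: the parser does not interpret
    assert parse_mcod_lines("*A419*A419*", "", "", "") == ["A419", "A419"]


def test_parse_mcod_lines_logs_anomalies():
    anomalies = []
    codes = parse_mcod_lines("*A419*bad!*", "*A01*A02*A03*A04*A05*A06*", "", "", anomalies=anomalies)
    assert codes[0] == "A419"
    assert len([c for c in codes if c.startswith("A0")]) == 5  # sixth slot ignored
    assert any("bad" in a for a in anomalies)
    assert any("slots" in a for a in anomalies)


@given(
    st.lists(
        st.one_of(st.just(""), st.from_regex(r"\*?([A-Z][0-9]{2,3}\*){1,7}", fullmatch=True)),
        min_size=4,
        max_size=4,
    )
)
def test_parse_mcod_lines_bounded(lines):
    assert len(parse_mcod_lines(*lines)) <= 20


def test_mcod_reader(tmp_path):
    header = ["ANO", "SEXO", "EDAD_TIPO", "EDAD_CANT", "LINHAA", "LINHAB", "LINHAC", "LINHAD"]
    rows = [
        ["2023", "1", "1", "70", "*I219*", "*A419*", "", ""],
        ["2023", "2", "1", "55", "", "", "", ""],  # no parseable cause
    ]
    path = tmp_path / "m.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=";")
        writer.writerow(header)
        writer.writerows(rows)
    records, rejects = read_mcod_table(path)
    assert len(records) == 1
    assert records[0].causes == ("I219", "A419")
    assert records[0].underlying_cause == "I219"
    assert rejects[0].reason == "no-valid-cause"


# ---------------------------------------------------------------------------
# population and standard weights
# ---------------------------------------------------------------------------

def test_uniform_population_gives_equal_weights():
    pop = PopulationTable(uniform_population())
    std = build_standard(pop, 2023, "01101")
    assert all(w == pytest.approx(0.2) for w in std.weights.values())
    assert sum(std.weights.values()) == pytest.approx(1.0, abs=1e-12)


def test_matched_weights_differ_between_comunas():
    cells = uniform_population(geography="A")
    cells.update({(2023, "B", g): 1000.0 * (i + 1) for i, g in enumerate(AGE_GROUPS)})
    pop = PopulationTable(cells)
    wa = build_standard(pop, 2023, "A").weights
    wb = build_standard(pop, 2023, "B").weights
    assert wa != wb
    assert build_standard(pop, 2023, None).weights != wa  # pooled differs too


def test_population_errors():
    pop = PopulationTable(uniform_population())
    with pytest.raises(RegistryError):
        build_standard(pop, 1999, "01101")  # absent year
    with pytest.raises(RegistryError):
        build_standard(pop, 2023, "nowhere")
    with pytest.raises(RegistryError):
        PopulationTable({(2023, "A", "<1"): -5.0})


def test_read_population_round_trip(tmp_path):
    path = tmp_path / "pop.csv"
    path.write_text(
        "year,geography,age_group,population\n"
        "2023,01101,<1,1200\n2023,01101,1-19,23800\n2023,01101,20-39,30000\n"
        "2023,01101,40-59,27000\n2023,01101,60+,18000\n"
    )
    pop = read_population(path)
    counts = pop.age_counts(2023, "01101")
    assert counts["60+"] == 18000
    assert sum(counts.values()) == 100_000
    # leading zeros preserved: geography codes are opaque strings
    assert pop.geographies == ["01101"]
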
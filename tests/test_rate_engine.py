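"""Crude rates, direct standardization and the gamma confidence interval."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sepsisburden.rate_engine import (
    RateError,
    StrataSpec,
    crude_rate,
    direct_standardize,
    estimates_to_frame,
    gamma_ci,
    max_rate_term,
    rate_table,
)
from sepsisburden.registry_io import AGE_GROUPS, PopulationTable, StandardPopulation

from conftest import make_record, uniform_population


def test_crude_rate_examples():
    assert crude_rate(50, 100_000) == pytest.approx(50.0)
    assert crude_rate(0, 12_345) == 0.0
    assert crude_rate(27, 43_210) == pytest.approx(1e5 * 27 / 43_210)
    with pytest.raises(RateError):
        crude_rate(1, 0)


def _std(weights):
    return StandardPopulation(dict(zip(AGE_GROUPS, weights)), "test")


def test_equal_rates_reduce_to_common_rate():
    std = _std([0.1, 0.2, 0.3, 0.25, 0.15])
    events = {g: 30.0 for g in AGE_GROUPS}
    pop = {g: 10_000.0 for g in AGE_GROUPS}
    asr, _ = direct_standardize(events, pop, std)
    assert asr == pytest.approx(300.0)


def test_standard_equal_to_own_structure_gives_crude_rate():
    pops = [1200.0, 23_800.0, 30_000.0, 27_000.0, 18_000.0]
    total = sum(pops)
    std = _std([p / total for p in pops])
    events = dict(zip(AGE_GROUPS, [1.0, 4.0, 10.0, 25.0, 60.0]))
    asr, _ = direct_standardize(events, dict(zip(AGE_GROUPS, pops)), std)
    assert asr == pytest.approx(crude_rate(100, total))


def test_two_group_hand_example():
    std = StandardPopulation({"20-39": 0.6, "60+": 0.4}, "toy")
    asr, var = direct_standardize({"20-39": 3, "60+": 8}, {"20-39": 1000, "60+": 500}, std)
    assert asr == pytest.approx(1e5 * (0.6 * 0.003 + 0.4 * 0.016))
    assert var == pytest.approx(1e10 * (0.36 * 3 / 1e6 + 0.16 * 8 / 2.5e5))


@settings(deadline=None)
@given(
    d=st.lists(st.integers(0, 50), min_size=3, max_size=3),
    n=st.lists(st.integers(100, 100_000), min_size=3, max_size=3),
    w_raw=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3),
)
def test_matches_brute_force_defining_sums(d, n, w_raw):
    """For <=3 groups the implementation agrees with a literal evaluation
    of the defining sums to 1e-12 relative."""
    groups = AGE_GROUPS[:3]
    total_w = sum(w_raw)
    weights = {g: w / total_w for g, w in zip(groups, w_raw)}
    # renormalize exactly so the invariant check passes
    correction = 1.0 - sum(weights.values())
    weights[groups[0]] += correction
    std = StandardPopulation(weights, "brute")
    asr, var = direct_standardize(dict(zip(groups, d)), dict(zip(groups, n)), std)
    brute_asr = 1e5 * sum(weights[g] * d_i / n_i for g, d_i, n_i in zip(groups, d, n))
    brute_var = 1e10 * sum(weights[g] ** 2 * d_i / n_i**2 for g, d_i, n_i in zip(groups, d, n))
    assert asr == pytest.approx(brute_asr, rel=1e-12)
    assert var == pytest.approx(brute_var, rel=1e-12)


def test_scale_invariance_of_asr():
    std = _std([0.2] * 5)
    events = dict(zip(AGE_GROUPS, [2.0, 5.0, 9.0, 12.0, 40.0]))
    pops = {g: 10_000.0 for g in AGE_GROUPS}
    asr1, var1 = direct_standardize(events, pops, std)
    scaled_events = {g: 7 * d for g, d in events.items()}
    scaled_pops = {g: 7 * n for g, n in pops.items()}
    asr2, var2 = direct_standardize(scaled_events, scaled_pops, std)
    assert asr2 == pytest.approx(asr1, rel=1e-12)
    assert var2 == pytest.approx(var1 / 7, rel=1e-12)


def test_events_without_population_error():
    std = _std([0.2] * 5)
    with pytest.raises(RateError):
        direct_standardize({"<1": 3.0}, {g: 0.0 for g in AGE_GROUPS}, std)


# ---------------------------------------------------------------------------
# gamma interval
# ---------------------------------------------------------------------------

def test_gamma_ci_zero_rate_lower_bound():
    lo, hi = gamma_ci(0.0, 0.0, w_max_rate_term=10.0)
    assert lo == 0.0
    assert hi > 0.0


def test_gamma_ci_contains_rate_and_widens_with_confidence():
    lo95, hi95 = gamma_ci(50.0, 500.0, 10.0, alpha=0.05)
    lo99, hi99 = gamma_ci(50.0, 500.0, 10.0, alpha=0.01)
    assert lo95 <= 50.0 <= hi95
    assert lo99 < lo95 and hi99 > hi95


def test_single_stratum_equals_exact_poisson_interval():
    """With one age group the gamma interval collapses to the exact
    chi-square interval for a Poisson count (d=5, n=1e4)."""
    d, n = 5, 1e4
    std = StandardPopulation({"60+": 1.0}, "single")
    asr, var = direct_standardize({"60+": d}, {"60+": n}, std)
    shift = max_rate_term({"60+": n}, std)
    lo, hi = gamma_ci(asr, var, shift)
    scale = 1e5 / n
    exact_lo = scale * stats.chi2.ppf(0.025, 2 * d) / 2
    exact_hi = scale * stats.chi2.ppf(0.975, 2 * (d + 1)) / 2
    assert lo == pytest.approx(exact_lo, rel=1e-10)
    assert hi == pytest.approx(exact_hi, rel=1e-10)


def test_gamma_ci_rejects_negative_inputs():
    with pytest.raises(RateError):
        gamma_ci(-1.0, 1.0, 1.0)
    with pytest.raises(RateError):
        gamma_ci(1.0, -1.0, 1.0)


# ---------------------------------------------------------------------------
# rate tables
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_world():
    pop = PopulationTable(
        {**uniform_population(geography="A"), **uniform_population(geography="B")}
    )
    records = [
        make_record(comuna="A", age_years=70, age_group="60+")
        for _ in range(20)
    ] + [
        make_record(comuna="B", age_years=30, age_group="20-39")
        for _ in range(5)
    ]
    return records, pop


def test_rate_table_by_geography(toy_world):
    records, pop = toy_world
    spec = StrataSpec(by=("geography",), event_kind="death")
    table = rate_table(records, pop, spec=spec, std_year=2023)
    by_geo = {e.stratum["geography"]: e for e in table}
    assert by_geo["A"].events == 20
    assert by_geo["A"].population_base == 50_000
    assert by_geo["A"].crude_rate == pytest.approx(40.0)
    # uniform population: standardized equals crude
    assert by_geo["A"].asr == pytest.approx(40.0)
    assert by_geo["B"].asr == pytest.approx(10.0)


def test_rate_table_empty_records(toy_world):
    _, pop = toy_world
    assert rate_table([], pop, spec=StrataSpec()) == []


def test_rate_table_age_specific_strata(toy_world):
    records, pop = toy_world
    spec = StrataSpec(by=("geography", "age_group"), event_kind="death")
    table = rate_table(records, pop, spec=spec, std_year=2023)
    est = next(e for e in table if e.stratum["geography"] == "A")
    assert est.stratum["age_group"] == "60+"
    assert est.asr == pytest.approx(1e5 * 20 / 10_000)


def test_rate_table_zero_population_stratum_errors(toy_world):
    records, pop = toy_world
    bad = records + [make_record(comuna="C")]
    with pytest.raises(Exception):
        rate_table(bad, pop, spec=StrataSpec(), std_year=2023)


def test_estimates_frame_column_order(toy_world):
    records, pop = toy_world
    table = rate_table(records, pop, spec=StrataSpec(), std_year=2023)
    frame = estimates_to_frame(table)
    assert list(frame.columns)[:1] == ["geography"]
    assert list(frame.columns)[1:] == [
        "events", "population", "crude_rate", "asr", "variance", "ci_low", "ci_high", "alpha",
    ]


def test_chapter_stratification(toy_world):
    records, pop = toy_world
    extra = [make_record(comuna="A", cause="C349"), make_record(comuna="A", cause="A009")]
    spec = StrataSpec(by=("chapter",), geography_level="country", event_kind="death")
    table = rate_table(records + extra, pop, spec=spec, std_year=2023)
    chapters = {e.stratum["chapter"] for e in table}
    assert {"I", "II"} <= chapters  # A00 -> chapter I, C34 -> chapter II
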
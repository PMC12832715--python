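"""The synthetic registry generator: determinism, expectations, recovery."""

import json
from pathlib import Path

import numpy as np
import pytest
from scipy import stats

from sepsisburden.registry_io import AGE_GROUPS, read_population, read_single_cause_table, read_mcod_table
from sepsisburden.synthetic_registry import (
    MCODTruth,
    MissingnessSpec,
    SyntheticTruth,
    default_truth,
    expected_summary,
    generate,
    generate_mcod,
    simulate_missing_counts,
)


def test_zero_rates_give_empty_event_tables(tmp_path):
    truth = default_truth()
    truth.rates = {k: (0.0, 0.0) for k in truth.rates}
    truth.background_asir = {}
    truth.background_asmr = {}
    paths = generate(truth, tmp_path)
    deaths, _ = read_single_cause_table(paths["deaths"], event_kind="death")
    discharges, _ = read_single_cause_table(paths["discharges"], event_kind="discharge_alive")
    assert deaths == [] and discharges == []
    # population intact
    pop = read_population(paths["population"])
    assert pop.geographies == sorted(truth.comunas)


def test_fixed_seed_byte_identical_output(tmp_path):
    a = tmp_path / "a"
    b = tmp_path / "b"
    generate(default_truth(seed=99), a)
    generate(default_truth(seed=99), b)
    for name in ("deaths.csv", "discharges.csv", "population.csv", "truth.json"):
        assert (a / name).read_bytes() == (b / name).read_bytes()
    c = tmp_path / "c"
    generate(default_truth(seed=100), c)
    assert (a / "deaths.csv").read_bytes() != (c / "deaths.csv").read_bytes()


def test_truth_serialization_round_trip():
    truth = default_truth()
    clone = SyntheticTruth.from_dict(json.loads(json.dumps(truth.to_dict())))
    assert clone.rates == truth.rates
    assert clone.regions == truth.regions
    assert clone.age_structure == truth.age_structure


def test_expected_summary_algebra():
    truth = default_truth()
    expected = expected_summary(truth)
    # a planted warning cell is listed as warning and nowhere else
    assert ["03102", "60+", "K659"] in expected["warning_strata"]
    assert ["01102", "60+", "A419"] in expected["excess_strata"]
    cell = expected["cells"]["01102|60+|A419"]
    n = round(truth.comuna_population["01102"] * truth.age_structure["01102"]["60+"])
    assert cell["expected_deaths"] == pytest.approx(450.0 * n / 1e5)
    assert cell["expected_discharges"] == pytest.approx(90.0 * n / 1e5)


def test_validation_catches_inconsistent_truth():
    truth = default_truth()
    truth.rates[("nowhere", "60+", "A419")] = (1.0, 1.0)
    with pytest.raises(ValueError):
        truth.validate()


def test_event_counts_match_poisson_expectations(registry_dir, truth):
    """Pooled z-scores of per-cell counts under the Poisson model look
    standard normal (Kolmogorov-Smirnov p > 0.01)."""
    records, _ = read_single_cause_table(registry_dir / "discharges.csv", event_kind="discharge_alive")
    counts: dict = {}
    for r in records:
        counts[(r.comuna_code, r.age_group, r.underlying_cause)] = counts.get(
            (r.comuna_code, r.age_group, r.underlying_cause), 0
        ) + 1
    zs = []
    for (comuna, age, code), (asir, _) in truth.rates.items():
        n = round(truth.comuna_population[comuna] * truth.age_structure[comuna][age])
        mean = asir * n / 1e5
        if mean < 10:  # normal approximation needs a moderate mean
            continue
        observed = counts.get((comuna, age, code), 0)
        zs.append((observed - mean) / np.sqrt(mean))
    assert len(zs) > 50
    _, p = stats.kstest(zs, "norm")
    assert p > 0.01


def test_mcar_missing_counts_scale_with_rate(rng):
    totals = {g: 10_000 for g in AGE_GROUPS}
    spec = MissingnessSpec(kind="mcar", rate=0.1)
    missing = simulate_missing_counts(totals, spec, rng)
    for g in AGE_GROUPS:
        assert 800 <= missing[g] <= 1200  # ~Binomial(10000, 0.1)
    none = simulate_missing_counts(totals, MissingnessSpec(), rng)
    assert all(v == 0 for v in none.values())


def test_missingness_injection_blanks_configured_variable(tmp_path):
    truth = default_truth(seed=5, missingness=MissingnessSpec(kind="mcar", rate=0.2))
    paths = generate(truth, tmp_path)
    _, rejects = read_single_cause_table(paths["discharges"], event_kind="discharge_alive")
    reasons = {r.reason for r in rejects}
    assert "missing-geography" in reasons


def test_mcod_f0_gives_identical_scod_and_mcod_counts(tmp_path, code_lists):
    from sepsisburden.sepsis_codes import is_sepsis_mcod, match_code

    truth = MCODTruth(seed=21, secondary_line_fraction=0.0)
    paths = generate_mcod(truth, tmp_path)
    records, _ = read_mcod_table(paths["mcod_deaths"])
    mcod_n = sum(is_sepsis_mcod(r, code_lists) for r in records)
    scod_n = sum(match_code(r.underlying_cause, code_lists).label == "explicit" for r in records)
    assert mcod_n == scod_n  # f=0: every sepsis code sits on the underlying line
    assert truth.expected_lambda() == 1.0


def test_mcod_expected_deaths_scale():
    truth = MCODTruth(secondary_line_fraction=0.25)
    assert truth.expected_deaths() == pytest.approx(47_488.0, rel=1e-6)
    assert truth.expected_lambda() == pytest.approx(4.0 / 3.0)
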
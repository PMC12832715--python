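"""Synthetic vital-registration and hospital-discharge registries.

Generates the three table dialects the pipeline consumes — single-cause
death and live-discharge tables, a multiple-cause (four certificate lines)
death table, and population projections — from a fully declared ground
truth, so that every pipeline stage can be tested for recovery without any
external download.

The statistical model mirrors what the analysis assumes and nothing more:
event counts per (geography, age group, code) cell are Poisson with mean
``true_rate * population / 1e5``; certificate-line placement of the sepsis
code is Bernoulli with the declared secondary-line fraction ``f`` (so the
single-cause view misses a fraction f of sepsis deaths and the expected
correction ratio is λ = 1/(1-f)); missingness is injected MCAR or with
age-dependent probabilities.  No demographic realism (migration, cohort
effects) is attempted.

The default scenario is deliberately sharp: cells are either clearly
contained (incidence well above mortality), clearly in excess, true
warnings (zero incidence with substantial mortality) or silent, so that the
excess/warning classification recovered from one simulated year matches the
declared truth with overwhelming probability.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .registry_io import AGE_GROUPS, SchemaConfig, age_group_of

__all__ = [
    "MissingnessSpec",
    "SyntheticTruth",
    "MCODTruth",
    "default_truth",
    "default_mcod_truth",
    "generate",
    "generate_mcod",
    "expected_summary",
    "simulate_missing_counts",
]

_AGE_SAMPLERS = {
    "<1": (0.0, 1.0),
    "1-19": (1.0, 20.0),
    "20-39": (20.0, 40.0),
    "40-59": (40.0, 60.0),
    "60+": (60.0, 95.0),
}


@dataclass(frozen=True)
class MissingnessSpec:
    """How to blank out one variable in the discharge table.

    ``kind``: "none", "mcar" (every row blanked with probability ``rate``)
    or "age-biased" (per-row probability ``age_probs[age_group]``).
    """

    variable: str = "comuna"
    kind: str = "none"
    rate: float = 0.0
    age_probs: Mapping[str, float] | None = None

    def probability(self, age_group: str) -> float:
        if self.kind == "none":
            return 0.0
        if self.kind == "mcar":
            return self.rate
        if self.kind == "age-biased":
            if self.age_probs is None:
                raise ValueError("age-biased missingness requires age_probs")
            return float(self.age_probs.get(age_group, 0.0))
        raise ValueError(f"unknown missingness kind {self.kind!r}")


@dataclass
class SyntheticTruth:
    """Declared ground truth for one simulated year of a country.

    ``rates`` maps (comuna, age_group, code) to (true ASIR, true ASMR) per
    100,000; cells absent from the map are zero.  ``age_structure`` gives
    per-comuna age-group shares (they differ across comunas so matched and
    national standards are distinguishable).  The reference-year population
    is the simulated year's scaled by ``growth_to_std_year``.
    """

    seed: int = 20_230
    year: int = 2023
    std_year: int = 2025
    regions: dict = field(default_factory=dict)  # region -> tuple of comunas
    comuna_population: dict = field(default_factory=dict)
    age_structure: dict = field(default_factory=dict)  # comuna -> {age: share}
    growth_to_std_year: float = 1.02
    rates: dict = field(default_factory=dict)  # (comuna, age, code) -> (asir, asmr)
    background_codes: tuple = ("I219", "C349", "E119", "I64", "J449", "V892")
    background_asir: dict = field(default_factory=dict)  # age -> rate
    background_asmr: dict = field(default_factory=dict)
    discharge_dead_fraction: float = 0.03
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)

    def validate(self) -> None:
        comunas = {c for cs in self.regions.values() for c in cs}
        if not comunas:
            raise ValueError("truth declares no comunas")
        if set(self.comuna_population) != comunas:
            raise ValueError("comuna_population keys must match the geography tree")
        for comuna, shares in self.age_structure.items():
            if comuna not in comunas:
                raise ValueError(f"age structure for unknown comuna {comuna!r}")
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ValueError(f"age shares for {comuna!r} do not sum to 1")
        for (comuna, age, code), (asir, asmr) in self.rates.items():
            if comuna not in comunas:
                raise ValueError(f"rate cell references unknown comuna {comuna!r}")
            if age not in AGE_GROUPS:
                raise ValueError(f"rate cell references unknown age group {age!r}")
            if asir < 0 or asmr < 0:
                raise ValueError(f"negative true rate at {(comuna, age, code)}")

    @property
    def comunas(self) -> list:
        return sorted(c for cs in self.regions.values() for c in cs)

    @property
    def codes(self) -> list:
        return sorted({code for (_, _, code) in self.rates})

    def region_of(self) -> dict:
        return {c: r for r, cs in self.regions.items() for c in cs}

    def population_cells(self) -> dict:
        """(year, comuna, age_group) -> count, for the simulated and the
        reference year."""
        cells = {}
        for comuna, total in self.comuna_population.items():
            shares = self.age_structure[comuna]
            for age in AGE_GROUPS:
                base = total * shares[age]
                cells[(self.year, comuna, age)] = round(base)
                cells[(self.std_year, comuna, age)] = round(base * self.growth_to_std_year)
        return cells

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rates"] = {
            "|".join(k): list(v) for k, v in self.rates.items()
        }
        d["regions"] = {r: list(cs) for r, cs in self.regions.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        d = dict(d)
        d["rates"] = {tuple(k.split("|")): tuple(v) for k, v in d["rates"].items()}
        d["regions"] = {r: tuple(cs) for r, cs in d["regions"].items()}
        d["background_codes"] = tuple(d["background_codes"])
        d["missingness"] = MissingnessSpec(**d["missingness"])
        return cls(**d)


def default_truth(
    seed: int = 20_230,
    secondary_warning_boost: float = 1.0,
    missingness: MissingnessSpec | None = None,
) -> SyntheticTruth:
    """The bundled study scenario: 3 regions, 8 comunas, 6 sepsis codes.

    Baseline cells carry incidence far above mortality (contained); planted
    departures are two excess cells and three warning cells (zero incidence
    with clearly positive mortality).  Infant incidence is set high enough
    that no baseline cell can plausibly flip to excess by sampling noise.
    """
    regions = {
        "R01": ("01101", "01102", "01103"),
        "R02": ("02101", "02102", "02103"),
        "R03": ("03101", "03102"),
    }
    comunas = [c for cs in regions.values() for c in cs]
    pop = {c: 100_000 for c in comunas}
    base_shares = np.array([0.012, 0.238, 0.300, 0.270, 0.180])
    age_structure = {}
    for i, comuna in enumerate(comunas):
        tilt = (i - 3.5) * 0.008  # elderly share varies across comunas
        shares = base_shares.copy()
        shares[4] += tilt
        shares[2] -= tilt
        age_structure[comuna] = dict(zip(AGE_GROUPS, (shares / shares.sum()).tolist()))

    codes = ("A419", "A410", "J180", "K659", "J960", "N390")
    # baseline true ASIR per code in the 60+ group; younger groups scaled.
    base_asir = {"A419": 400.0, "A410": 150.0, "J180": 300.0, "K659": 120.0, "J960": 200.0, "N390": 250.0}
    age_scale = {"<1": 6.0, "1-19": 0.5, "20-39": 0.4, "40-59": 0.7, "60+": 1.0}
    rates: dict = {}
    for comuna in comunas:
        for code in codes:
            for age in AGE_GROUPS:
                asir = base_asir[code] * age_scale[age]
                asmr = 0.10 * asir if age == "60+" else 0.0  # deaths concentrate in the elderly
                rates[(comuna, age, code)] = (asir, asmr)

    # planted excess: mortality well above incidence, counts large enough
    # that the empirical ratio exceeds 1 essentially always.
    rates[("01102", "60+", "A419")] = (90.0, 450.0)
    rates[("01103", "40-59", "J180")] = (60.0, 300.0)
    # planted warnings: zero incidence, substantial mortality.
    rates[("03102", "60+", "K659")] = (0.0, 60.0 * secondary_warning_boost)
    rates[("03102", "60+", "J960")] = (0.0, 60.0 * secondary_warning_boost)
    rates[("02103", "40-59", "N390")] = (0.0, 50.0 * secondary_warning_boost)
    # silent cells: one comuna with no N390 signal at all outside 60+.
    for age in ("<1", "1-19", "20-39", "40-59"):
        rates[("03101", age, "N390")] = (0.0, 0.0)

    truth = SyntheticTruth(
        seed=seed,
        regions=regions,
        comuna_population=pop,
        age_structure=age_structure,
        rates=rates,
        background_asir={"<1": 4000.0, "1-19": 1500.0, "20-39": 2500.0, "40-59": 4000.0, "60+": 8000.0},
        background_asmr={"<1": 80.0, "1-19": 20.0, "20-39": 60.0, "40-59": 250.0, "60+": 2500.0},
        missingness=missingness or MissingnessSpec(),
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _sample_age_fields(rng: np.random.Generator, age_group: str) -> tuple[str, str]:
    """(age_type code, magnitude) within a bin; infants use months."""
    lo, hi = _AGE_SAMPLERS[age_group]
    if age_group == "<1":
        return "2", str(int(rng.integers(0, 12)))  # months
    return "1", str(int(rng.integers(int(lo), int(hi))))


def _event_rows(
    rng: np.random.Generator,
    truth: SyntheticTruth,
    which: str,  # "asir" or "asmr"
) -> list[list[str]]:
    """Expand Poisson cell counts into registry rows (unshuffled)."""
    region_of = truth.region_of()
    idx = 0 if which == "asir" else 1
    rows: list[list[str]] = []
    background = truth.background_asir if which == "asir" else truth.background_asmr
    for comuna in truth.comunas:
        total = truth.comuna_population[comuna]
        shares = truth.age_structure[comuna]
        for age in AGE_GROUPS:
            n = round(total * shares[age])
            if n <= 0:
                continue
            cells = [
                (code, truth.rates.get((comuna, age, code), (0.0, 0.0))[idx])
                for code in truth.codes
            ]
            bg_rate = background.get(age, 0.0)
            if bg_rate > 0:
                per_code = bg_rate / len(truth.background_codes)
                cells.extend((code, per_code) for code in truth.background_codes)
            for code, rate in cells:
                if rate <= 0:
                    continue
                count = rng.poisson(rate * n / 1e5)
                for _ in range(count):
                    sex = "1" if rng.random() < 0.5 else "2"
                    age_type, age_val = _sample_age_fields(rng, age)
                    rows.append(
                        [str(truth.year), sex, age_type, age_val, region_of[comuna], comuna, code]
                    )
    return rows


def _inject_missingness(
    rng: np.random.Generator,
    rows: list[list[str]],
    truth: SyntheticTruth,
    column_index: Mapping[str, int],
) -> None:
    spec = truth.missingness
    if spec.kind == "none":
        return
    col = column_index[spec.variable]
    age_type_i, age_i = column_index["age_type"], column_index["age"]
    for row in rows:
        age_years = float(row[age_i]) if row[age_type_i] == "1" else 0.0
        p = spec.probability(age_group_of(age_years))
        if p > 0 and rng.random() < p:
            row[col] = ""


def generate(truth: SyntheticTruth, outdir: str | Path, schema: SchemaConfig | None = None) -> dict:
    """Write the full synthetic registry bundle; returns file paths.

    Produces ``deaths.csv``, ``discharges.csv`` (single-cause dialect),
    ``population.csv``, ``region_lookup.csv`` and ``truth.json`` (the
    declared truth plus its analytic expectations).  Output is
    deterministic for a fixed truth (byte-identical files).
    """
    truth.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = schema or SchemaConfig()
    cols = schema.columns
    rng = np.random.default_rng(truth.seed)

    header = [cols["year"], cols["sex"], cols["age_type"], cols["age"],
              cols["region"], cols["comuna"], cols["cause"], cols["outcome"]]
    column_index = {"year": 0, "sex": 1, "age_type": 2, "age": 3, "region": 4, "comuna": 5, "cause": 6}

    death_rows = _event_rows(rng, truth, "asmr")
    for row in death_rows:
        row.append("2")  # outcome column present but unused for deaths

    discharge_rows = _event_rows(rng, truth, "asir")
    for row in discharge_rows:
        row.append(schema.alive_codes[0])
    # a slice of in-hospital deaths the discharge reader must exclude
    n_dead = rng.binomial(len(discharge_rows), truth.discharge_dead_fraction)
    for _ in range(int(n_dead)):
        base = discharge_rows[int(rng.integers(len(discharge_rows)))]
        row = list(base)
        row[-1] = "2"
        discharge_rows.append(row)
    _inject_missingness(rng, discharge_rows, truth, column_index)

    paths = {
        "deaths": outdir / "deaths.csv",
        "discharges": outdir / "discharges.csv",
        "population": outdir / "population.csv",
        "region_lookup": outdir / "region_lookup.csv",
        "truth": outdir / "truth.json",
    }
    for key, rows in (("deaths", death_rows), ("discharges", discharge_rows)):
        with open(paths[key], "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter=schema.delimiter)
            writer.writerow(header)
            writer.writerows(rows)

    with open(paths["population"], "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "geography", "age_group", "population"])
        for (year, comuna, age), count in sorted(truth.population_cells().items()):
            writer.writerow([year, comuna, age, count])

    with open(paths["region_lookup"], "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["comuna", "region"])
        for comuna, region in sorted(truth.region_of().items()):
            writer.writerow([comuna, region])

    ledger = {"truth": truth.to_dict(), "expected": expected_summary(truth)}
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)

    return {k: str(v) for k, v in paths.items()}


def expected_summary(truth: SyntheticTruth) -> dict:
    """Closed-form expectations implied by the declared truth.

    Per (comuna, age_group, code) cell: expected discharge and death counts
    and the EM state implied by the true rates (at the cell level the
    standardized rate equals the true rate, so states follow directly).
    """
    cells = {}
    excess, warning, silent = [], [], []
    for (comuna, age, code), (asir, asmr) in sorted(truth.rates.items()):
        n = round(truth.comuna_population[comuna] * truth.age_structure[comuna][age])
        cells["|".join((comuna, age, code))] = {
            "expected_discharges": asir * n / 1e5,
            "expected_deaths": asmr * n / 1e5,
            "true_asir": asir,
            "true_asmr": asmr,
        }
        key = [comuna, age, code]
        if asir > 0 and asmr / asir > 1:
            excess.append(key)
        elif asir == 0 and asmr > 0:
            warning.append(key)
        elif asir == 0 and asmr == 0:
            silent.append(key)
    return {
        "cells": cells,
        "excess_strata": excess,
        "warning_strata": warning,
        "silent_strata": silent,
    }


def simulate_missing_counts(
    total_by_group: Mapping[str, int],
    spec: MissingnessSpec,
    rng: np.random.Generator,
) -> dict:
    """Draw per-group missing counts under a missingness spec.

    Binomial per group with the spec's per-row probability — the sampling
    model behind the registry-level injection, exposed directly so that
    calibration experiments (many replicates of the goodness-of-fit test)
    do not need to re-expand full registries.
    """
    return {
        g: int(rng.binomial(int(n), spec.probability(g)))
        for g, n in total_by_group.items()
    }


# ---------------------------------------------------------------------------
# multiple-cause registry
# ---------------------------------------------------------------------------

@dataclass
class MCODTruth:
    """Ground truth for a DATASUS-like multiple-cause death registry.

    ``secondary_line_fraction`` f is the probability that a sepsis death
    carries its explicit sepsis code only on a non-underlying line (line B),
    with a background code as the underlying cause — exactly the records a
    single-cause reading misses, so the expected correction ratio is
    λ = 1/(1-f) and the expected relative bias (vs the multiple-cause rate)
    is 100·f percent.
    """

    seed: int = 77
    years: tuple = (2022, 2023)
    sexes: tuple = ("1", "2")
    pop_by_age: dict = field(
        default_factory=lambda: {"<1": 60_000, "1-19": 1_200_000, "20-39": 1_600_000, "40-59": 1_400_000, "60+": 940_000}
    )
    sepsis_asmr_by_age: dict = field(
        default_factory=lambda: {"<1": 120.0, "1-19": 15.0, "20-39": 40.0, "40-59": 180.0, "60+": 900.0}
    )
    background_asmr_by_age: dict = field(
        default_factory=lambda: {"<1": 150.0, "1-19": 30.0, "20-39": 90.0, "40-59": 400.0, "60+": 3000.0}
    )
    secondary_line_fraction: float = 0.0
    explicit_codes: tuple = ("A419", "A410", "A414", "A409")
    background_codes: tuple = ("I219", "C349", "I64", "J449", "E149")
    comorbidity_codes: tuple = ("I10", "E119", "N179", "J960", "R571")

    def validate(self) -> None:
        if not 0.0 <= self.secondary_line_fraction <= 1.0:
            raise ValueError("secondary_line_fraction must be in [0, 1]")

    def expected_lambda(self) -> float:
        return 1.0 / (1.0 - self.secondary_line_fraction)

    def expected_deaths(self) -> float:
        per_sex_year = sum(
            rate * n / 1e5
            for rate, n in zip(self.sepsis_asmr_by_age.values(), self.pop_by_age.values())
        )
        return per_sex_year * len(self.sexes) * len(self.years)


def generate_mcod(truth: MCODTruth, outdir: str | Path, schema: SchemaConfig | None = None) -> dict:
    """Write ``mcod_deaths.csv`` + ``mcod_population.csv`` for the external
    multiple-cause registry; returns file paths.

    Sepsis deaths always carry their explicit code somewhere on lines A-B;
    with probability f it sits on line B behind a background underlying
    cause.  Comorbidity codes (including organ-dysfunction codes that the
    explicit-only multiple-cause rule must ignore) are sprinkled on later
    lines, some with a trailing "X" placeholder to exercise trimming.
    """
    truth.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = schema or SchemaConfig()
    cols = schema.mcod_columns
    rng = np.random.default_rng(truth.seed)

    header = [cols["year"], cols["sex"], cols["age_type"], cols["age"],
              cols["line_a"], cols["line_b"], cols["line_c"], cols["line_d"]]
    rows: list[list[str]] = []
    f = truth.secondary_line_fraction
    for year in truth.years:
        for sex in truth.sexes:
            for age, n in truth.pop_by_age.items():
                n_sepsis = rng.poisson(truth.sepsis_asmr_by_age[age] * n / 1e5)
                n_bg = rng.poisson(truth.background_asmr_by_age[age] * n / 1e5)
                for _ in range(n_sepsis):
                    code = truth.explicit_codes[int(rng.integers(len(truth.explicit_codes)))]
                    bg = truth.background_codes[int(rng.integers(len(truth.background_codes)))]
                    comorb = truth.comorbidity_codes[int(rng.integers(len(truth.comorbidity_codes)))]
                    if len(comorb) == 3 and rng.random() < 0.5:
                        comorb += "X"  # placeholder variant
                    if f > 0 and rng.random() < f:
                        line_a, line_b = f"*{bg}*", f"*{code}*{comorb}*"
                    else:
                        line_a, line_b = f"*{code}*", f"*{comorb}*"
                    age_type, age_val = _sample_age_fields(rng, age)
                    rows.append([str(year), sex, age_type, age_val, line_a, line_b, "", ""])
                for _ in range(n_bg):
                    bg = truth.background_codes[int(rng.integers(len(truth.background_codes)))]
                    age_type, age_val = _sample_age_fields(rng, age)
                    rows.append([str(year), sex, age_type, age_val, f"*{bg}*", "", "", ""])

    paths = {"mcod_deaths": outdir / "mcod_deaths.csv", "mcod_population": outdir / "mcod_population.csv"}
    with open(paths["mcod_deaths"], "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=schema.delimiter)
        writer.writerow(header)
        writer.writerows(rows)
    with open(paths["mcod_population"], "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "geography", "age_group", "population"])
        for year in (*truth.years, max(truth.years) + 1):
            # one extra projection year serves as the standardization reference
            for age, n in truth.pop_by_age.items():
                writer.writerow([year, "EXT", age, n * len(truth.sexes)])
    return {k: str(v) for k, v in paths.items()}


def default_mcod_truth(seed: int = 77, secondary_line_fraction: float = 0.25) -> MCODTruth:
    return MCODTruth(seed=seed, secondary_line_fraction=secondary_line_fraction)
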
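"""Crude and directly age-standardized rates with gamma confidence intervals.

Rates are expressed per 100,000 population.  Direct standardization uses the
five harmonized age bins with weights from a reference ("standard")
population year, either *matched* (each geography standardized to its own
reference-year age structure) or *national* (one common structure, required
when variances must be comparable across geographies, as in pairwise
Z-tests).

The variance model is Poisson on event counts, the model behind the
gamma/chi-squared interval of Fay & Feuer (1997) for standardized rates:

    asr = 1e5 * sum_a w_a * d_a / n_a
    var = 1e10 * sum_a w_a^2 * d_a / n_a^2

with the upper confidence bound computed from the distribution shifted by
the largest single-count contribution ``max_a 1e5 * w_a / n_a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .icd import chapter_of
from .registry_io import (
    AGE_GROUPS,
    PersonRecord,
    PopulationTable,
    StandardPopulation,
    build_standard,
)

__all__ = [
    "RateEstimate",
    "StrataSpec",
    "crude_rate",
    "direct_standardize",
    "max_rate_term",
    "gamma_ci",
    "rate_table",
    "estimates_to_frame",
]

PER = 1e5


class RateError(ValueError):
    pass


@dataclass(frozen=True)
class RateEstimate:
    """Events, denominator and (standardized) rate for one stratum."""

    stratum: Mapping[str, object]
    events: int
    population_base: float
    crude_rate: float
    asr: float
    variance: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.asr + 1e-9):
            raise RateError(f"ci_low {self.ci_low} > asr {self.asr}")
        if self.ci_high < self.asr - 1e-9:
            raise RateError(f"ci_high {self.ci_high} < asr {self.asr}")


def crude_rate(events: float, population: float) -> float:
    """Events per 100,000 population."""
    if population <= 0:
        raise RateError(f"population must be positive, got {population}")
    if events < 0:
        raise RateError(f"events must be non-negative, got {events}")
    return PER * events / population


def direct_standardize(
    age_events: Mapping[str, float],
    age_pop: Mapping[str, float],
    std: StandardPopulation,
) -> tuple[float, float]:
    """Directly standardized rate and its Poisson variance (per 1e5, 1e5^2).

    Age groups absent from ``age_events`` contribute zero events; a group
    with events but no population is an error.
    """
    asr = 0.0
    var = 0.0
    for group, w in std.weights.items():
        d = float(age_events.get(group, 0.0))
        n = float(age_pop.get(group, 0.0))
        if d < 0 or n < 0:
            raise RateError(f"negative input in age group {group}")
        if n == 0:
            if d > 0:
                raise RateError(f"events with zero population in age group {group}")
            continue
        asr += w * d / n
        var += (w / n) ** 2 * d
    return PER * asr, PER * PER * var


def max_rate_term(age_pop: Mapping[str, float], std: StandardPopulation) -> float:
    """Largest single-count rate contribution ``max_a 1e5 * w_a / n_a``,
    the shift term of the gamma interval's upper bound."""
    terms = [
        PER * w / float(age_pop[g])
        for g, w in std.weights.items()
        if w > 0 and float(age_pop.get(g, 0.0)) > 0
    ]
    if not terms:
        raise RateError("no age group with positive weight and population")
    return max(terms)


def gamma_ci(asr, variance, w_max_rate_term, alpha: float = 0.05):
    """Fay-Feuer gamma/chi-squared confidence interval for a standardized
    rate.

    Lower bound: quantile of Gamma(shape=asr^2/var, scale=var/asr).  Upper
    bound: quantile of the distribution shifted by the largest single-count
    term ``w = w_max_rate_term``, i.e. Gamma with moments (asr + w,
    var + w^2).  A zero rate pins the lower bound at 0 while the upper bound
    comes from the shift term alone.  Accepts scalars or equal-shape arrays.
    """
    asr = np.asarray(asr, dtype=float)
    variance = np.asarray(variance, dtype=float)
    w = np.asarray(w_max_rate_term, dtype=float)
    if np.any(asr < 0) or np.any(variance < 0) or np.any(w <= 0):
        raise RateError("gamma_ci requires asr >= 0, variance >= 0, shift term > 0")
    if not (0 < alpha < 1):
        raise RateError(f"alpha must be in (0,1), got {alpha}")

    pos = asr > 0
    lo = np.zeros_like(asr)
    if np.any(pos):
        shape = np.where(pos, asr**2 / np.where(pos, variance, 1.0), 1.0)
        scale = np.where(pos, np.where(pos, variance, 1.0) / np.where(pos, asr, 1.0), 1.0)
        lo = np.where(pos, stats.gamma.ppf(alpha / 2.0, a=shape, scale=scale), 0.0)

    asr_u = asr + w
    var_u = variance + w**2
    hi = stats.gamma.ppf(1.0 - alpha / 2.0, a=asr_u**2 / var_u, scale=var_u / asr_u)
    if lo.ndim == 0:
        return float(lo), float(hi)
    return lo, hi


# ---------------------------------------------------------------------------
# stratified rate tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrataSpec:
    """What to stratify rates by.

    ``by`` is an ordered subset of {"year", "sex", "geography", "age_group",
    "code", "chapter"}.  ``geography_level`` selects the geography id used
    for both grouping and population lookup: "comuna", "region" (requires a
    comuna->region lookup) or "country".  When "age_group" appears in
    ``by``, standardization degenerates to the age-specific rate (weight 1
    on that group).
    """

    by: tuple = ("geography",)
    geography_level: str = "comuna"
    event_kind: str = "death"

    _ALLOWED = ("year", "sex", "geography", "age_group", "code", "chapter")

    def __post_init__(self):
        bad = [k for k in self.by if k not in self._ALLOWED]
        if bad:
            raise RateError(f"unknown strata keys {bad}")
        if self.geography_level not in ("comuna", "region", "country"):
            raise RateError(f"unknown geography level {self.geography_level!r}")


def records_to_frame(records: Iterable[PersonRecord]) -> pd.DataFrame:
    rows = [
        {
            "year": r.event_year,
            "sex": r.sex,
            "age_group": r.age_group,
            "region": r.region_code,
            "comuna": r.comuna_code,
            "code": r.underlying_cause,
            "event_kind": r.event_kind,
        }
        for r in records
    ]
    frame = pd.DataFrame(
        rows,
        columns=["year", "sex", "age_group", "region", "comuna", "code", "event_kind"],
    )
    return frame


def rate_table(
    records: Sequence[PersonRecord],
    pop: PopulationTable,
    std_mode: str = "matched",
    spec: StrataSpec | None = None,
    std_year: int = 2025,
    alpha: float = 0.05,
    region_lookup: Mapping[str, str] | None = None,
) -> list[RateEstimate]:
    """One :class:`RateEstimate` per stratum observed in ``records``.

    The population denominator for a stratum is the annual projection for
    the stratum's geography and year(s), summed per age group (annual
    projections serve directly as person-years).  The population table is
    keyed by comuna; region- and country-level denominators are aggregated
    through ``region_lookup`` / pooling.  Strata with zero population raise.
    """
    if spec is None:
        spec = StrataSpec()
    if std_mode not in ("matched", "national"):
        raise RateError(f"unknown std_mode {std_mode!r}")

    frame = records_to_frame(r for r in records if r.event_kind == spec.event_kind)
    if frame.empty:
        return []

    if spec.geography_level == "comuna":
        frame["geography"] = frame["comuna"]
        geo_pop = pop
    elif spec.geography_level == "region":
        if region_lookup:
            frame["geography"] = frame["comuna"].map(region_lookup).fillna(frame["region"])
            geo_pop = pop.aggregate(region_lookup)
        else:
            frame["geography"] = frame["region"]
            geo_pop = pop
    else:
        frame["geography"] = "ALL"
        geo_pop = pop.aggregate({g: "ALL" for g in pop.geographies})

    if "chapter" in spec.by:
        frame["chapter"] = frame["code"].map(chapter_of)

    years_in_data = sorted(frame["year"].unique())
    national_std = build_standard(geo_pop, std_year, None, label=f"national-{std_year}")

    keys = list(spec.by)
    group_cols = keys + ([] if "age_group" in keys else ["age_group"])
    counts = frame.groupby(group_cols, observed=True).size().reset_index(name="d")
    strata = counts[keys].drop_duplicates().to_dict("records") if keys else [{}]

    estimates: list[RateEstimate] = []
    for stratum in strata:
        sub = counts
        for k, v in stratum.items():
            sub = sub[sub[k] == v]
        age_events = {g: 0.0 for g in AGE_GROUPS}
        for g, d in zip(sub["age_group"], sub["d"]):
            age_events[g] += float(d)

        geo_scope = stratum.get("geography")  # None => all geographies
        years = [stratum["year"]] if "year" in stratum else years_in_data
        age_pop = {g: 0.0 for g in AGE_GROUPS}
        for y in years:
            year_pop = geo_pop.age_counts(y, geo_scope)
            for g in AGE_GROUPS:
                age_pop[g] += year_pop[g]
        n_total = sum(age_pop.values())
        if n_total <= 0:
            raise RateError(f"zero population for stratum {stratum}")

        if "age_group" in stratum:
            group = stratum["age_group"]
            std = StandardPopulation({group: 1.0}, reference_label="age-specific")
            age_pop = {group: age_pop[group]}
            if age_pop[group] <= 0:
                raise RateError(f"zero population for stratum {stratum}")
            n_total = age_pop[group]
            age_events = {group: age_events.get(group, 0.0)}
        elif std_mode == "national":
            std = national_std
        else:
            std = build_standard(geo_pop, std_year, geo_scope)

        events = int(sum(age_events.values()))
        asr, var = direct_standardize(age_events, age_pop, std)
        shift = max_rate_term(age_pop, std)
        lo, hi = gamma_ci(asr, var, shift, alpha=alpha)
        estimates.append(
            RateEstimate(
                stratum=dict(stratum),
                events=events,
                population_base=n_total,
                crude_rate=crude_rate(events, n_total),
                asr=asr,
                variance=var,
                ci_low=lo,
                ci_high=hi,
                alpha=alpha,
            )
        )
    return estimates


def estimates_to_frame(estimates: Sequence[RateEstimate]) -> pd.DataFrame:
    """Flatten estimates to a DataFrame with stratum keys first and the
    fixed column order d, n, crude, asr, var, lo, hi."""
    rows = []
    for est in estimates:
        row = dict(est.stratum)
        row.update(
            events=est.events,
            population=est.population_base,
            crude_rate=est.crude_rate,
            asr=est.asr,
            variance=est.variance,
            ci_low=est.ci_low,
            ci_high=est.ci_high,
            alpha=est.alpha,
        )
        rows.append(row)
    return pd.DataFrame(rows)
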
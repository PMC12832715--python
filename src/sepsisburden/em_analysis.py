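"""Excess-of-mortality (EM) analysis.

EM is the ratio of the age-standardized mortality rate to the
age-standardized incidence rate, ASMR/ASIR, computed per stratum (geography
x age group x ICD-10 code, or aggregates).  Cells with EM > 1 flag places
where sepsis deaths outpace recorded sepsis incidence — where sepsis is not
being contained.  Four states partition the cells:

* ``excess``    — ASIR > 0 and ASMR/ASIR > 1;
* ``contained`` — ASIR > 0 and ASMR/ASIR <= 1 (1 itself is contained: the
  operator is strictly ">");
* ``warning``   — ASIR = 0 with ASMR > 0: EM is undefined (division by
  zero), but mortality without incidence is the strongest possible signal;
* ``silent``    — ASMR = ASIR = 0, kept distinct so matrices can tell
  no-signal cells from contained ones.

The default warning rule triggers on any positive ASMR with zero ASIR; a
stricter ``warning_mode="gt1"`` requiring ASMR > 1 is available for
sensitivity analyses (sub-threshold mortality then counts as contained).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .rate_engine import RateEstimate

__all__ = ["EMResult", "compute_em", "em_table", "rank_excess", "heatmap_matrix"]

STATES = ("contained", "excess", "warning", "silent")


class EMError(ValueError):
    pass


@dataclass(frozen=True)
class EMResult:
    stratum: Mapping[str, object]
    asmr: float
    asir: float
    em: float | None
    state: str


def compute_em(
    asmr: float,
    asir: float,
    stratum: Mapping[str, object] | None = None,
    warning_mode: str = "gt0",
) -> EMResult:
    """Classify one (ASMR, ASIR) pair; ``em`` is None when ASIR = 0."""
    if asmr < 0 or asir < 0:
        raise EMError(f"rates must be non-negative, got asmr={asmr}, asir={asir}")
    if warning_mode not in ("gt0", "gt1"):
        raise EMError(f"unknown warning_mode {warning_mode!r}")
    stratum = dict(stratum or {})
    if asir > 0:
        em = asmr / asir
        state = "excess" if em > 1.0 else "contained"
        return EMResult(stratum, asmr, asir, em, state)
    threshold = 0.0 if warning_mode == "gt0" else 1.0
    if asmr > threshold:
        return EMResult(stratum, asmr, asir, None, "warning")
    if asmr > 0:  # gt1 mode, sub-threshold mortality
        return EMResult(stratum, asmr, asir, None, "contained")
    return EMResult(stratum, asmr, asir, None, "silent")


def _key(stratum: Mapping[str, object]) -> tuple:
    return tuple(sorted(stratum.items()))


def em_table(
    mortality: Sequence[RateEstimate],
    incidence: Sequence[RateEstimate],
    warning_mode: str = "gt0",
) -> list[EMResult]:
    """Pair mortality and incidence estimates stratum-by-stratum.

    Both inputs must share a stratification schema (same key names); the
    result covers the union of strata, with the missing side treated as
    rate 0 — that is exactly how warning cells arise.
    """
    schemas = {frozenset(e.stratum) for e in mortality} | {frozenset(e.stratum) for e in incidence}
    if len(schemas) > 1:
        raise EMError(f"inconsistent stratification schemas: {sorted(map(sorted, schemas))}")
    mort = {_key(e.stratum): e for e in mortality}
    inc = {_key(e.stratum): e for e in incidence}
    results = []
    for key in sorted(set(mort) | set(inc), key=repr):
        asmr = mort[key].asr if key in mort else 0.0
        asir = inc[key].asr if key in inc else 0.0
        stratum = dict(key)
        results.append(compute_em(asmr, asir, stratum, warning_mode=warning_mode))
    return results


def rank_excess(table: Sequence[EMResult]) -> list[EMResult]:
    """Rank cells by the magnitude of the excess.

    Excess cells first, descending EM; warning cells after them (their EM
    is unquantifiable but the signal is real), descending ASMR.  Contained
    and silent cells are excluded.
    """
    excess = sorted((r for r in table if r.state == "excess"), key=lambda r: -r.em)
    warning = sorted((r for r in table if r.state == "warning"), key=lambda r: -r.asmr)
    return excess + warning


def heatmap_matrix(
    table: Sequence[EMResult],
    age_filter: Sequence[str] | None = None,
    row_key: str = "geography",
    col_key: str = "code",
) -> pd.DataFrame:
    """Geography x code matrix of EM values for excess cells only.

    ``age_filter`` restricts to the given age groups when the table is
    age-stratified; if more than one age group survives the filter, columns
    become (age_group, code) pairs.  Absent combinations are NaN (rendered
    blank).
    """
    rows = []
    for r in table:
        if r.state != "excess":
            continue
        if age_filter is not None and r.stratum.get("age_group") not in set(age_filter):
            continue
        rows.append(
            {
                "row": r.stratum.get(row_key, "all"),
                "col": r.stratum.get(col_key, "all"),
                "age_group": r.stratum.get("age_group"),
                "em": r.em,
            }
        )
    if not rows:
        return pd.DataFrame()
    frame = pd.DataFrame(rows)
    multi_age = frame["age_group"].notna().any() and frame["age_group"].nunique() > 1
    columns = ["age_group", "col"] if multi_age else "col"
    return frame.pivot_table(index="row", columns=columns, values="em", aggfunc="max")
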
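"""Single-cause undercount correction via the MCOD/SCOD ratio λ.

Registries that record only the underlying cause of death miss sepsis that
appears on other certificate lines.  Where a comparable registry publishes
all certificate lines, a country-level correction ratio

    λ(sex, year) = ASR_MCOD / ASR_SCOD

can be computed on that external registry and applied to single-cause rates
elsewhere.  Because every SCOD-positive record is also MCOD-positive,
λ >= 1.  Relative bias is reported, by default, as the shortfall relative
to the multiple-cause ("true") rate:

    bias% = 100 * (1 - 1/λ)        ("vs-mcod", the default)

with the alternative convention 100 * (λ - 1) ("vs-scod") behind a flag.
λ is treated as a fixed constant when applied: corrected rates and their
confidence bounds are scaled, with no propagation of λ's own uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import pandas as pd

from .rate_engine import RateEstimate

__all__ = ["LambdaEntry", "LambdaTable", "compute_lambda", "apply_lambda"]

BIAS_MODES = ("vs-mcod", "vs-scod")


class LambdaError(ValueError):
    pass


def _bias_pct(lam: float, mode: str) -> float:
    return 100.0 * (1.0 - 1.0 / lam) if mode == "vs-mcod" else 100.0 * (lam - 1.0)


@dataclass(frozen=True)
class LambdaEntry:
    sex: str
    year: int
    asr_mcod: float
    asr_scod: float
    lam: float | None  # None when SCOD rate is zero (incomputable)
    relative_bias_pct: float | None


@dataclass
class LambdaTable:
    entries: list = field(default_factory=list)
    bias_mode: str = "vs-mcod"

    def get(self, sex: str, year: int) -> LambdaEntry:
        for e in self.entries:
            if e.sex == sex and e.year == year:
                return e
        raise LambdaError(f"no lambda entry for sex={sex!r}, year={year}")

    def yearly_summary(self) -> pd.DataFrame:
        """Per-year means across sexes of λ and relative bias (computable
        cells only)."""
        rows = [
            {"year": e.year, "lam": e.lam, "relative_bias_pct": e.relative_bias_pct}
            for e in self.entries
            if e.lam is not None
        ]
        if not rows:
            return pd.DataFrame(columns=["year", "lam", "relative_bias_pct"])
        return pd.DataFrame(rows).groupby("year", as_index=False).mean()

    def pooled_lambda(self) -> float:
        lams = [e.lam for e in self.entries if e.lam is not None]
        if not lams:
            raise LambdaError("no computable lambda entries")
        return sum(lams) / len(lams)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])


def compute_lambda(
    mcod_rates: Sequence[RateEstimate],
    scod_rates: Sequence[RateEstimate],
    bias_mode: str = "vs-mcod",
) -> LambdaTable:
    """Per-(sex, year) λ from paired multiple- and single-cause rate tables.

    Both tables must be stratified by sex and year with matching keys.
    Cells with a zero single-cause rate are marked incomputable, excluded
    from summaries, and warned about.
    """
    if bias_mode not in BIAS_MODES:
        raise LambdaError(f"unknown bias_mode {bias_mode!r}")

    def index(rates) -> dict:
        out = {}
        for est in rates:
            if "sex" not in est.stratum or "year" not in est.stratum:
                raise LambdaError("lambda tables require (sex, year) stratification")
            out[(est.stratum["sex"], est.stratum["year"])] = est
        return out

    mcod = index(mcod_rates)
    scod = index(scod_rates)
    if set(mcod) != set(scod):
        raise LambdaError(
            f"mismatched (sex, year) keys: {sorted(set(mcod) ^ set(scod))}"
        )
    table = LambdaTable(bias_mode=bias_mode)
    for (sex, year) in sorted(mcod):
        m, s = mcod[(sex, year)].asr, scod[(sex, year)].asr
        if s <= 0:
            warnings.warn(
                f"SCOD rate is zero for sex={sex!r}, year={year}; lambda incomputable",
                stacklevel=2,
            )
            table.entries.append(LambdaEntry(sex, year, m, s, None, None))
            continue
        lam = m / s
        table.entries.append(LambdaEntry(sex, year, m, s, lam, _bias_pct(lam, bias_mode)))
    return table


def apply_lambda(
    scod_rates: Sequence[RateEstimate],
    lambda_table: LambdaTable,
    matching: str = "by-sex-year",
) -> list[RateEstimate]:
    """Scale single-cause rates (and their CI bounds) by λ.

    ``matching`` selects the λ used per stratum: "by-sex-year" (exact key),
    "by-year" (yearly mean across sexes) or "pooled" (grand mean).  A
    stratum with no defined λ under the chosen matching is an error.
    """
    if matching not in ("by-sex-year", "by-year", "pooled"):
        raise LambdaError(f"unknown matching {matching!r}")
    yearly: Mapping[int, float] = {}
    if matching == "by-year":
        summary = lambda_table.yearly_summary()
        yearly = dict(zip(summary["year"], summary["lam"]))
    pooled = lambda_table.pooled_lambda() if matching == "pooled" else None

    corrected = []
    for est in scod_rates:
        if matching == "by-sex-year":
            entry = lambda_table.get(est.stratum.get("sex"), est.stratum.get("year"))
            lam = entry.lam
            if lam is None:
                raise LambdaError(f"lambda incomputable for stratum {est.stratum}")
        elif matching == "by-year":
            year = est.stratum.get("year")
            if year not in yearly:
                raise LambdaError(f"no yearly lambda for year {year}")
            lam = yearly[year]
        else:
            lam = pooled
        corrected.append(
            replace(
                est,
                crude_rate=est.crude_rate * lam,
                asr=est.asr * lam,
                variance=est.variance * lam**2,
                ci_low=est.ci_low * lam,
                ci_high=est.ci_high * lam,
            )
        )
    return corrected
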
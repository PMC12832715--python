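"""Reading, validation and harmonization of registry tables.

Three table dialects are consumed:

* single-cause tables (deaths and hospital discharges) in a DEIS-like
  schema: one row per event with year, sex, age unit + magnitude, region and
  comuna of residency, and a single ICD-10 code;
* multiple-cause death tables in a DATASUS-like schema: four certificate
  lines (A-D), each carrying up to five asterisk-demarcated ICD-10 codes;
* population projections by year x geography x age group.

Every reader is row-wise: a row either becomes a harmonized
:class:`PersonRecord` or lands in a reject log with a reason code, so
``rows_in == records_out + rejects`` always holds.  Column names, delimiter,
encoding, sex and age-unit codebooks and geography sentinels are all supplied
by a schema config (YAML), because source registries do not share a codebook.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .icd import ICDCodeError, normalize_icd10

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_GROUPS",
    "PersonRecord",
    "RejectedRow",
    "PopulationTable",
    "StandardPopulation",
    "SchemaConfig",
    "harmonize_age",
    "normalize_icd10",
    "read_single_cause_table",
    "write_single_cause_table",
    "parse_mcod_lines",
    "read_mcod_table",
    "read_population",
    "build_standard",
    "write_reject_log",
]

#: The five harmonized age bins used throughout the pipeline.  The last bin
#: is [60, inf): sixty-year-olds belong to "60+".
AGE_GROUPS: tuple[str, ...] = ("<1", "1-19", "20-39", "40-59", "60+")

_AGE_EDGES = (1.0, 20.0, 40.0, 60.0)

#: Years per unit for each supported age-magnitude unit.
_UNIT_YEARS: Mapping[str, float] = {
    "years": 1.0,
    "months": 1.0 / 12.0,
    "days": 1.0 / 365.25,
    "hours": 1.0 / 8766.0,
}

SEXES = ("male", "female", "undetermined")
EVENT_KINDS = ("death", "discharge_alive")


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class PersonRecord:
    """One harmonized death or live-discharge event."""

    event_year: int
    sex: str
    age_years: float
    age_group: str
    region_code: str
    comuna_code: str
    causes: tuple[str, ...]
    event_kind: str

    def __post_init__(self):
        if self.sex not in SEXES:
            raise RegistryError(f"unknown sex {self.sex!r}")
        if self.event_kind not in EVENT_KINDS:
            raise RegistryError(f"unknown event kind {self.event_kind!r}")
        if self.age_group not in AGE_GROUPS:
            raise RegistryError(f"unknown age group {self.age_group!r}")
        if not self.causes:
            raise RegistryError("causes must be non-empty")

    @property
    def underlying_cause(self) -> str:
        """First listed cause: the underlying cause of death / primary
        cause of hospitalization."""
        return self.causes[0]


@dataclass(frozen=True)
class RejectedRow:
    row_number: int
    reason: str
    raw_fields: Mapping[str, str]


def harmonize_age(age_type: str, age_value: float) -> tuple[float, str]:
    """Scale an (unit, magnitude) age to years and bin it.

    ``age_type`` is one of ``years``/``months``/``days``/``hours``.  Ages
    expressed in sub-year units always fall in the "<1" bin — registries use
    those units only for infants.  Returns ``(age_years, age_group)``.
    """
    if age_type not in _UNIT_YEARS:
        raise RegistryError(f"unknown age unit {age_type!r}")
    value = float(age_value)
    if value < 0:
        raise RegistryError(f"negative age {age_value!r}")
    age_years = value * _UNIT_YEARS[age_type]
    if age_type != "years":
        return age_years, "<1"
    if age_years < _AGE_EDGES[0]:
        return age_years, AGE_GROUPS[0]
    if age_years < _AGE_EDGES[1]:
        return age_years, AGE_GROUPS[1]
    if age_years < _AGE_EDGES[2]:
        return age_years, AGE_GROUPS[2]
    if age_years < _AGE_EDGES[3]:
        return age_years, AGE_GROUPS[3]
    return age_years, AGE_GROUPS[4]


def age_group_of(age_years: float) -> str:
    """Bin an age already expressed in years."""
    return harmonize_age("years", age_years)[1]


# ---------------------------------------------------------------------------
# schema configuration
# ---------------------------------------------------------------------------

_DEFAULT_COLUMNS = {
    "year": "ANO",
    "sex": "SEXO",
    "age_type": "EDAD_TIPO",
    "age": "EDAD_CANT",
    "region": "REGION",
    "comuna": "COMUNA",
    "cause": "DIAG1",
    "outcome": "COND_EGRESO",
}

_DEFAULT_MCOD_COLUMNS = {
    "year": "ANO",
    "sex": "SEXO",
    "age_type": "EDAD_TIPO",
    "age": "EDAD_CANT",
    "line_a": "LINHAA",
    "line_b": "LINHAB",
    "line_c": "LINHAC",
    "line_d": "LINHAD",
}


@dataclass
class SchemaConfig:
    """Column mapping + codebooks for one registry dialect.

    ``sentinels`` maps semantic field names to literal values meaning
    "undetermined" (e.g. comuna ``99999`` = ignored, ``88888`` = foreign
    national); rows carrying them never reach analysis-ready records.
    """

    columns: dict = field(default_factory=lambda: dict(_DEFAULT_COLUMNS))
    mcod_columns: dict = field(default_factory=lambda: dict(_DEFAULT_MCOD_COLUMNS))
    sex_codes: dict = field(default_factory=lambda: {"1": "male", "2": "female", "9": "undetermined"})
    age_type_codes: dict = field(default_factory=lambda: {"1": "years", "2": "months", "3": "days", "4": "hours"})
    alive_codes: tuple = ("1",)
    sentinels: dict = field(default_factory=lambda: {"comuna": ["99999", "88888"], "region": ["99"]})
    delimiter: str = ";"
    encoding: str = "utf-8"
    fallback_encoding: str = "latin-1"

    REQUIRED = ("year", "sex", "age_type", "age", "region", "comuna", "cause")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("columns", "mcod_columns", "sex_codes", "age_type_codes", "sentinels"):
            if key in raw:
                getattr(cfg, key).update({str(k): v for k, v in raw[key].items()})
        if "alive_codes" in raw:
            cfg.alive_codes = tuple(str(c) for c in raw["alive_codes"])
        for key in ("delimiter", "encoding", "fallback_encoding"):
            if key in raw:
                setattr(cfg, key, raw[key])
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = [f for f in self.REQUIRED if f not in self.columns]
        if missing:
            raise RegistryError(f"schema_config missing column mappings for {missing}")


def _open_text(path: str | Path, schema: SchemaConfig) -> io.TextIOWrapper:
    try:
        fh = open(path, "r", encoding=schema.encoding, newline="")
        fh.read(4096)
        fh.seek(0)
        return fh
    except UnicodeDecodeError:
        return open(path, "r", encoding=schema.fallback_encoding, newline="")


# ---------------------------------------------------------------------------
# single-cause reader / writer
# ---------------------------------------------------------------------------

def _row_to_record(
    row: Mapping[str, str],
    schema: SchemaConfig,
    event_kind: str,
) -> tuple[PersonRecord | None, str | None]:
    """Validate one raw row; return (record, None) or (None, reason)."""
    cols = schema.columns

    def get(fieldname: str) -> str:
        return str(row.get(cols[fieldname], "") or "").strip()

    if event_kind == "discharge_alive":
        outcome_col = cols.get("outcome")
        if outcome_col is not None and outcome_col in row:
            if str(row[outcome_col]).strip() not in schema.alive_codes:
                return None, "outcome-not-alive"

    year_raw = get("year")
    try:
        year = int(year_raw)
    except ValueError:
        return None, "bad-year"

    sex = schema.sex_codes.get(get("sex"))
    if sex is None:
        return None, "bad-sex-code"

    age_unit = schema.age_type_codes.get(get("age_type"))
    if age_unit is None:
        return None, "bad-age-type"
    try:
        age_years, age_group = harmonize_age(age_unit, float(get("age")))
    except (ValueError, RegistryError):
        return None, "bad-age"

    region = get("region")
    comuna = get("comuna")
    if not region or not comuna:
        return None, "missing-geography"
    if comuna in set(map(str, schema.sentinels.get("comuna", []))):
        return None, "sentinel-geography"
    if region in set(map(str, schema.sentinels.get("region", []))):
        return None, "sentinel-geography"

    try:
        cause = normalize_icd10(get("cause"))
    except ICDCodeError as exc:
        return None, f"bad-icd10:{exc.reason}"

    return (
        PersonRecord(
            event_year=year,
            sex=sex,
            age_years=age_years,
            age_group=age_group,
            region_code=region,
            comuna_code=comuna,
            causes=(cause,),
            event_kind=event_kind,
        ),
        None,
    )


def read_single_cause_table(
    path: str | Path,
    schema: SchemaConfig | None = None,
    event_kind: str = "death",
) -> tuple[list[PersonRecord], list[RejectedRow]]:
    """Read a DEIS-like single-cause table into harmonized records.

    The discharge reader (``event_kind="discharge_alive"``) keeps only rows
    whose outcome code marks a live discharge; everything else goes to the
    reject log.  Row numbers in the log are 1-based over data rows.
    """
    schema = schema or SchemaConfig()
    schema.validate()
    if event_kind not in EVENT_KINDS:
        raise RegistryError(f"unknown event kind {event_kind!r}")
    records: list[PersonRecord] = []
    rejects: list[RejectedRow] = []
    with _open_text(path, schema) as fh:
        reader = csv.DictReader(fh, delimiter=schema.delimiter)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty file, no records read", stacklevel=2)
            return [], []
        n = 0
        for i, row in enumerate(reader, start=1):
            n = i
            record, reason = _row_to_record(row, schema, event_kind)
            if record is None:
                rejects.append(RejectedRow(i, reason, dict(row)))
            else:
                records.append(record)
        if n == 0:
            warnings.warn(f"{path}: no data rows", stacklevel=2)
    return records, rejects


def write_single_cause_table(
    records: Iterable[PersonRecord],
    path: str | Path,
    schema: SchemaConfig | None = None,
) -> None:
    """Write analysis-ready records back into the single-cause dialect.

    Ages are written in years (unit code for "years"), so a subsequent
    :func:`read_single_cause_table` round-trips every field exactly.
    """
    schema = schema or SchemaConfig()
    cols = schema.columns
    sex_rev = {v: k for k, v in schema.sex_codes.items()}
    unit_rev = {v: k for k, v in schema.age_type_codes.items()}
    header = [cols["year"], cols["sex"], cols["age_type"], cols["age"],
              cols["region"], cols["comuna"], cols["cause"], cols["outcome"]]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=schema.delimiter)
        writer.writerow(header)
        for rec in records:
            outcome = schema.alive_codes[0] if rec.event_kind == "discharge_alive" else "2"
            writer.writerow([
                rec.event_year,
                sex_rev[rec.sex],
                unit_rev["years"],
                repr(rec.age_years),
                rec.region_code,
                rec.comuna_code,
                rec.underlying_cause,
                outcome,
            ])


def write_reject_log(rejects: Sequence[RejectedRow], path: str | Path) -> None:
    """Persist a reject log as JSON-lines, one object per rejected row."""
    with open(path, "w", encoding="utf-8") as fh:
        for rej in rejects:
            fh.write(json.dumps(asdict(rej), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# multiple-cause parsing
# ---------------------------------------------------------------------------

def parse_mcod_lines(
    line_a: str,
    line_b: str,
    line_c: str,
    line_d: str,
    anomalies: list[str] | None = None,
) -> list[str]:
    """Extract ICD-10 codes from four death-certificate cause lines.

    Each line holds up to five asterisk-demarcated slots (e.g.
    ``"*A419*J960*"``).  Codes are returned in certificate order (line A
    first); duplicates are preserved — interpretation belongs to the
    classifier.  Malformed slots and lines with more than five slots are
    recorded in ``anomalies`` (if given) and skipped/truncated, never fatal.
    """
    codes: list[str] = []
    for label, line in zip("ABCD", (line_a, line_b, line_c, line_d)):
        if line is None:
            continue
        slots = [s for s in str(line).split("*") if s.strip()]
        if len(slots) > 5:
            if anomalies is not None:
                anomalies.append(f"line {label}: {len(slots)} slots, extra ignored")
            slots = slots[:5]
        for slot in slots:
            try:
                codes.append(normalize_icd10(slot))
            except ICDCodeError as exc:
                if anomalies is not None:
                    anomalies.append(f"line {label}: bad slot {slot!r} ({exc.reason})")
    return codes


def read_mcod_table(
    path: str | Path,
    schema: SchemaConfig | None = None,
    geography: str = "EXT",
) -> tuple[list[PersonRecord], list[RejectedRow]]:
    """Read a DATASUS-like multiple-cause death table.

    Produces death records whose ``causes`` concatenate lines A→D; the first
    code of line A plays the role of the underlying cause.  Rows with no
    parseable code at all are rejected.
    """
    schema = schema or SchemaConfig()
    cols = schema.mcod_columns
    records: list[PersonRecord] = []
    rejects: list[RejectedRow] = []
    with _open_text(path, schema) as fh:
        reader = csv.DictReader(fh, delimiter=schema.delimiter)
        if reader.fieldnames is None:
            warnings.warn(f"{path}: empty file, no records read", stacklevel=2)
            return [], []
        for i, row in enumerate(reader, start=1):
            def get(name: str) -> str:
                return str(row.get(cols[name], "") or "").strip()

            try:
                year = int(get("year"))
            except ValueError:
                rejects.append(RejectedRow(i, "bad-year", dict(row)))
                continue
            sex = schema.sex_codes.get(get("sex"))
            if sex is None:
                rejects.append(RejectedRow(i, "bad-sex-code", dict(row)))
                continue
            age_unit = schema.age_type_codes.get(get("age_type"))
            if age_unit is None:
                rejects.append(RejectedRow(i, "bad-age-type", dict(row)))
                continue
            try:
                age_years, age_group = harmonize_age(age_unit, float(get("age")))
            except (ValueError, RegistryError):
                rejects.append(RejectedRow(i, "bad-age", dict(row)))
                continue
            causes = parse_mcod_lines(get("line_a"), get("line_b"), get("line_c"), get("line_d"))
            if not causes:
                rejects.append(RejectedRow(i, "no-valid-cause", dict(row)))
                continue
            records.append(
                PersonRecord(
                    event_year=year,
                    sex=sex,
                    age_years=age_years,
                    age_group=age_group,
                    region_code=geography,
                    comuna_code=geography,
                    causes=tuple(causes),
                    event_kind="death",
                )
            )
    return records, rejects


# ---------------------------------------------------------------------------
# population projections & standard population
# ---------------------------------------------------------------------------

@dataclass
class PopulationTable:
    """Population counts by (year, geography_id, age_group).

    Geography identifiers are opaque strings (leading zeros preserved).
    """

    cells: dict

    def __post_init__(self):
        for key, count in self.cells.items():
            if count < 0:
                raise RegistryError(f"negative population at {key}")

    @property
    def years(self) -> list[int]:
        return sorted({k[0] for k in self.cells})

    @property
    def geographies(self) -> list[str]:
        return sorted({k[1] for k in self.cells})

    def age_counts(self, year: int, geographies=None) -> dict[str, float]:
        """Population per age group for one year, summed over a geography
        scope (a single id, an iterable of ids, or None for all)."""
        if geographies is None:
            scope = None
        elif isinstance(geographies, str):
            scope = {geographies}
        else:
            scope = set(geographies)
        out = {g: 0.0 for g in AGE_GROUPS}
        seen = False
        for (y, geo, age), count in self.cells.items():
            if y != year:
                continue
            if scope is not None and geo not in scope:
                continue
            out[age] += count
            seen = True
        if not seen:
            raise RegistryError(f"population has no cells for year {year}, scope {geographies!r}")
        return out

    def aggregate(self, mapping: Mapping[str, str]) -> "PopulationTable":
        """Re-key geographies through ``mapping`` (e.g. comuna -> region),
        summing counts; ids absent from the mapping are dropped."""
        cells: dict = {}
        for (y, geo, age), count in self.cells.items():
            if geo not in mapping:
                continue
            key = (y, mapping[geo], age)
            cells[key] = cells.get(key, 0.0) + count
        return PopulationTable(cells)


@dataclass(frozen=True)
class StandardPopulation:
    """Age-group weights of a reference population; weights sum to 1."""

    weights: Mapping[str, float]
    reference_label: str

    def __post_init__(self):
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-12:
            raise RegistryError(f"standard weights sum to {total}, not 1")
        if any(w < 0 for w in self.weights.values()):
            raise RegistryError("negative standard weight")


def read_population(path: str | Path, delimiter: str = ",") -> PopulationTable:
    """Read a population projection CSV with columns
    ``year,geography,age_group,population``."""
    cells: dict = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        required = {"year", "geography", "age_group", "population"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise RegistryError(f"population file {path} must have columns {sorted(required)}")
        for row in reader:
            age = row["age_group"].strip()
            if age not in AGE_GROUPS:
                raise RegistryError(f"unknown age group {age!r} in population file")
            key = (int(row["year"]), row["geography"].strip(), age)
            cells[key] = cells.get(key, 0.0) + float(row["population"])
    return PopulationTable(cells)


def build_standard(
    pop: PopulationTable,
    year: int,
    geography_scope=None,
    label: str | None = None,
) -> StandardPopulation:
    """Derive standard-population weights from a projection year.

    "Matched" standardization passes the stratum's own geography as scope;
    "national" passes None (all geographies pooled).
    """
    counts = pop.age_counts(year, geography_scope)
    total = sum(counts.values())
    if total <= 0:
        raise RegistryError(f"zero total population for year {year}, scope {geography_scope!r}")
    weights = {a: c / total for a, c in counts.items()}
    if label is None:
        scope_txt = "national" if geography_scope is None else str(geography_scope)
        label = f"{scope_txt}-{year}"
    return StandardPopulation(weights=weights, reference_label=label)
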
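"""End-to-end orchestration of the burden pipeline.

Stages mirror the analysis flow: simulate (or point at) a registry bundle,
ingest and harmonize, audit completeness, compute age-standardized rates,
integrate them into excess-of-mortality tables, derive and apply the
multiple-cause correction ratio, and run the sensitivity/uncertainty
machinery.  Every stage is a plain function taking a :class:`RunConfig`;
the CLI wraps them one-to-one.  The run config is serialized verbatim into
the output directory so a run is reproducible from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias_correction, completeness_audit, em_analysis, rate_engine, registry_io, sepsis_codes, synthetic_registry, uncertainty
from .registry_io import AGE_GROUPS, SchemaConfig

try:
    PACKAGE_VERSION = version("sepsisburden")
except PackageNotFoundError:  # running from a source tree
    PACKAGE_VERSION = "0+unknown"

__all__ = ["RunConfig", "run_simulate", "run_ingest", "run_audit", "run_rates",
           "run_em", "run_lambda", "run_psa", "run_ztest", "run_report", "run_all"]


@dataclass
class RunConfig:
    data_dir: str = "data"
    out_dir: str = "out"
    seed: int = 0
    std_mode: str = "matched"
    std_year: int = 2025
    alpha: float = 0.05
    n_iter: int = 10_000
    warning_mode: str = "gt0"
    bias_mode: str = "vs-mcod"
    implicit_rule: str = "or"
    code_lists_path: str | None = None
    schema_path: str | None = None

    def schema(self) -> SchemaConfig:
        if self.schema_path:
            return SchemaConfig.from_yaml(self.schema_path)
        return SchemaConfig()

    def code_lists(self) -> sepsis_codes.CodeLists:
        if self.code_lists_path:
            return sepsis_codes.load_code_lists(self.code_lists_path)
        return sepsis_codes.default_code_lists()

    def save(self) -> None:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "run_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        with open(out / "RUN_INFO.json", "w", encoding="utf-8") as fh:
            json.dump({"package": "sepsisburden", "version": PACKAGE_VERSION, "seed": self.seed}, fh, indent=1)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_simulate(cfg: RunConfig) -> dict:
    """Generate the default synthetic registry bundle into ``data_dir``."""
    truth = synthetic_registry.default_truth(seed=cfg.seed or 20_230)
    paths = synthetic_registry.generate(truth, cfg.data_dir)
    mcod_truth = synthetic_registry.default_mcod_truth(seed=(cfg.seed or 20_230) + 1)
    paths.update(synthetic_registry.generate_mcod(mcod_truth, cfg.data_dir))
    with open(Path(cfg.data_dir) / "mcod_truth.json", "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(mcod_truth), fh, indent=1, sort_keys=True)
    return paths


@dataclass
class Ingested:
    deaths: list
    discharges: list
    mcod: list = field(default_factory=list)
    pop: registry_io.PopulationTable | None = None
    mcod_pop: registry_io.PopulationTable | None = None
    region_lookup: dict = field(default_factory=dict)
    reject_counts: dict = field(default_factory=dict)


def run_ingest(cfg: RunConfig, write: bool = True) -> Ingested:
    """Read and harmonize the registry bundle in ``data_dir``."""
    data = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = cfg.schema()
    deaths, rej_d = registry_io.read_single_cause_table(data / "deaths.csv", schema, "death")
    discharges, rej_i = registry_io.read_single_cause_table(
        data / "discharges.csv", schema, "discharge_alive"
    )
    pop = registry_io.read_population(data / "population.csv")
    lookup = {}
    lookup_path = data / "region_lookup.csv"
    if lookup_path.exists():
        frame = pd.read_csv(lookup_path, dtype=str)
        lookup = dict(zip(frame["comuna"], frame["region"]))
    mcod: list = []
    rej_m: list = []
    mcod_pop = None
    if (data / "mcod_deaths.csv").exists():
        mcod, rej_m = registry_io.read_mcod_table(data / "mcod_deaths.csv", schema)
        mcod_pop = registry_io.read_population(data / "mcod_population.csv")
    if write:
        registry_io.write_reject_log(rej_d, out / "rejects_deaths.jsonl")
        registry_io.write_reject_log(rej_i, out / "rejects_discharges.jsonl")
        if mcod:
            registry_io.write_reject_log(rej_m, out / "rejects_mcod.jsonl")
    return Ingested(
        deaths=deaths,
        discharges=discharges,
        mcod=mcod,
        pop=pop,
        mcod_pop=mcod_pop,
        region_lookup=lookup,
        reject_counts={"deaths": len(rej_d), "discharges": len(rej_i), "mcod": len(rej_m)},
    )


def run_audit(cfg: RunConfig) -> completeness_audit.CompletenessReport:
    """Completeness audit of the raw discharge table + randomness test of
    any flagged variable's missingness across decadal age bins."""
    data = Path(cfg.data_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema = cfg.schema()
    raw = pd.read_csv(data / "discharges.csv", delimiter=schema.delimiter, dtype=str)
    cols = schema.columns
    sentinels = {
        cols[var]: vals for var, vals in schema.sentinels.items() if cols.get(var) in raw.columns
    }
    report = completeness_audit.audit(raw, sentinels)
    _write_csv(report.to_frame(), out / "completeness.csv")

    gof_payload = {}
    flagged = [v.variable for v in report.flagged]
    if flagged:
        # decadal age bins for the randomness test
        age_years = pd.to_numeric(raw[cols["age"]], errors="coerce").fillna(0.0)
        is_years = raw[cols["age_type"]].astype(str) == "1"
        age_years = age_years.where(is_years, 0.0)
        decade = (age_years // 10).clip(upper=9).astype(int)
        labels = decade.map(lambda d: f"{d*10}-{d*10+9}" if d < 9 else "90+")
        for var in flagged:
            miss = raw[var].isna() | (raw[var].astype(str).str.strip() == "")
            total = labels.value_counts().to_dict()
            missing = labels[miss].value_counts().to_dict()
            try:
                gof = completeness_audit.gof_missing_randomness(missing, total)
            except completeness_audit.AuditError as exc:
                gof_payload[var] = {"error": str(exc)}
                continue
            gof_payload[var] = {
                "chi2": gof.chi2, "df": gof.df, "p_value": gof.p_value,
                "groups": gof.groups,
            }
    gof_payload["collinear_missing"] = report.collinear_missing
    with open(out / "gof_missing.json", "w", encoding="utf-8") as fh:
        json.dump(gof_payload, fh, indent=1)
    return report


def _sepsis_records(records, lists, implicit_rule):
    return [r for r in records if sepsis_codes.is_sepsis_scod(r, lists, implicit_rule)]


def run_rates(cfg: RunConfig, ingested: Ingested | None = None) -> dict:
    """Sepsis rate tables at comuna level: all-codes and code x age level."""
    ingested = ingested or run_ingest(cfg, write=False)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lists = cfg.code_lists()
    deaths = _sepsis_records(ingested.deaths, lists, cfg.implicit_rule)
    discharges = _sepsis_records(ingested.discharges, lists, cfg.implicit_rule)

    tables = {}
    for name, spec in {
        "comuna": rate_engine.StrataSpec(by=("geography",), event_kind="death"),
        "comuna_incidence": rate_engine.StrataSpec(by=("geography",), event_kind="discharge_alive"),
        "cell_mortality": rate_engine.StrataSpec(by=("geography", "age_group", "code"), event_kind="death"),
        "cell_incidence": rate_engine.StrataSpec(by=("geography", "age_group", "code"), event_kind="discharge_alive"),
    }.items():
        source = deaths if spec.event_kind == "death" else discharges
        tables[name] = rate_engine.rate_table(
            source, ingested.pop, std_mode=cfg.std_mode, spec=spec,
            std_year=cfg.std_year, alpha=cfg.alpha, region_lookup=ingested.region_lookup,
        )
        _write_csv(rate_engine.estimates_to_frame(tables[name]), out / f"rates_{name}.csv")
    return tables


def run_em(cfg: RunConfig, tables: dict | None = None) -> dict:
    """Excess-of-mortality tables, ranking and heatmap matrix."""
    tables = tables or run_rates(cfg)
    out = Path(cfg.out_dir)
    comuna = em_analysis.em_table(tables["comuna"], tables["comuna_incidence"], cfg.warning_mode)
    cells = em_analysis.em_table(tables["cell_mortality"], tables["cell_incidence"], cfg.warning_mode)
    ranking = em_analysis.rank_excess(cells)
    for name, table in (("em_comuna", comuna), ("em_cells", cells)):
        frame = pd.DataFrame(
            [{**r.stratum, "asmr": r.asmr, "asir": r.asir, "em": r.em, "state": r.state} for r in table]
        )
        _write_csv(frame, out / f"{name}.csv")
    _write_csv(
        pd.DataFrame([{**r.stratum, "em": r.em, "asmr": r.asmr, "state": r.state} for r in ranking]),
        out / "em_ranking.csv",
    )
    matrix = em_analysis.heatmap_matrix(cells)
    matrix.to_csv(out / "em_matrix.csv", float_format="%.10g", lineterminator="\n")
    return {"comuna": comuna, "cells": cells, "ranking": ranking, "matrix": matrix}


def lambda_from_mcod(
    mcod_records,
    mcod_pop,
    lists,
    std_year: int,
    bias_mode: str = "vs-mcod",
    alpha: float = 0.05,
):
    """λ table from a multiple-cause registry: rates by (sex, year) under
    the multiple-cause (explicit, any line) and single-cause (underlying
    cause only) sepsis rules."""
    mcod_pos = [r for r in mcod_records if sepsis_codes.is_sepsis_mcod(r, lists)]
    scod_pos = [
        r for r in mcod_records
        if sepsis_codes.match_code(r.underlying_cause, lists).label == "explicit"
    ]
    spec = rate_engine.StrataSpec(by=("sex", "year"), geography_level="country", event_kind="death")
    kwargs = dict(pop=mcod_pop, std_mode="national", spec=spec, std_year=std_year, alpha=alpha)
    mcod_rates = rate_engine.rate_table(mcod_pos, **kwargs)
    scod_rates = rate_engine.rate_table(scod_pos, **kwargs)
    return bias_correction.compute_lambda(mcod_rates, scod_rates, bias_mode=bias_mode)


def run_lambda(cfg: RunConfig, ingested: Ingested | None = None) -> bias_correction.LambdaTable:
    """Compute the correction ratio from the external multiple-cause table."""
    ingested = ingested or run_ingest(cfg, write=False)
    if not ingested.mcod:
        raise FileNotFoundError("no mcod_deaths.csv in the data directory")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    std_year = max(ingested.mcod_pop.years)
    table = lambda_from_mcod(
        ingested.mcod, ingested.mcod_pop, cfg.code_lists(), std_year,
        bias_mode=cfg.bias_mode, alpha=cfg.alpha,
    )
    _write_csv(table.to_frame(), out / "lambda.csv")
    _write_csv(table.yearly_summary(), out / "lambda_yearly.csv")
    return table


def run_psa(cfg: RunConfig, tables: dict | None = None) -> dict:
    """PSA of expected sepsis deaths and discharges at country scale."""
    tables = tables or run_rates(cfg)
    out = Path(cfg.out_dir)
    results = {}
    for name, key in (("deaths", "comuna"), ("discharges", "comuna_incidence")):
        ests = tables[key]
        pops = [e.population_base for e in ests]
        rates = [e.asr for e in ests]
        res = uncertainty.psa(pops, rates, n_iter=cfg.n_iter, seed=cfg.seed)
        results[name] = res
        with open(out / f"psa_{name}.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(res), fh, indent=1)
    return results


def run_ztest(cfg: RunConfig, ingested: Ingested | None = None) -> dict:
    """Pairwise Z-test matrices across comunas under the national standard."""
    ingested = ingested or run_ingest(cfg, write=False)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lists = cfg.code_lists()
    results = {}
    for name, (records, kind) in {
        "asmr": (ingested.deaths, "death"),
        "asir": (ingested.discharges, "discharge_alive"),
    }.items():
        sepsis = _sepsis_records(records, lists, cfg.implicit_rule)
        ests = rate_engine.rate_table(
            sepsis, ingested.pop, std_mode="national",
            spec=rate_engine.StrataSpec(by=("geography",), event_kind=kind),
            std_year=cfg.std_year, alpha=cfg.alpha,
        )
        matrix = uncertainty.pairwise_matrix(ests, alpha=cfg.alpha)
        results[name] = matrix
        matrix.p_frame().to_csv(out / f"ztest_p_{name}.csv", float_format="%.6g", lineterminator="\n")
    with open(out / "ztest_summary.json", "w", encoding="utf-8") as fh:
        json.dump(
            {k: {"significant_fraction_pct": m.significant_fraction_pct, "alpha": m.alpha}
             for k, m in results.items()},
            fh, indent=1,
        )
    return results


def run_report(cfg: RunConfig, em_results: dict | None = None, ztests: dict | None = None) -> list:
    """Render heatmaps (EM matrix, p-value matrices) as PNG + SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(cfg.out_dir)
    em_results = em_results or run_em(cfg)
    written = []
    matrix = em_results["matrix"]
    if not matrix.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        data = matrix.to_numpy(dtype=float)
        im = ax.imshow(data, cmap="YlOrRd", aspect="auto")
        ax.set_xticks(range(matrix.shape[1]))
        ax.set_xticklabels(["/".join(map(str, c)) if isinstance(c, tuple) else str(c) for c in matrix.columns], rotation=90)
        ax.set_yticks(range(matrix.shape[0]))
        ax.set_yticklabels(matrix.index)
        ax.set_title("Excess of mortality (ASMR/ASIR > 1)")
        fig.colorbar(im, ax=ax, label="EM")
        fig.tight_layout()
        for ext in ("png", "svg"):
            path = out / f"em_heatmap.{ext}"
            fig.savefig(path)
            written.append(str(path))
        plt.close(fig)
    if ztests:
        for name, matrix_ in ztests.items():
            fig, ax = plt.subplots(figsize=(5, 4))
            im = ax.imshow(matrix_.p, cmap="viridis", vmin=0, vmax=1)
            ax.set_xticks(range(len(matrix_.labels)))
            ax.set_xticklabels(matrix_.labels, rotation=90)
            ax.set_yticks(range(len(matrix_.labels)))
            ax.set_yticklabels(matrix_.labels)
            ax.set_title(f"Pairwise Z-test p-values ({name.upper()})")
            fig.colorbar(im, ax=ax, label="p")
            fig.tight_layout()
            path = out / f"ztest_p_{name}.png"
            fig.savefig(path)
            written.append(str(path))
            plt.close(fig)
    return written


def run_all(cfg: RunConfig) -> None:
    """A→D flow: simulate, ingest, audit, rates, EM, λ, PSA, Z-tests, report."""
    cfg.save()
    if not (Path(cfg.data_dir) / "deaths.csv").exists():
        run_simulate(cfg)
    ingested = run_ingest(cfg)
    run_audit(cfg)
    tables = run_rates(cfg, ingested)
    em_results = run_em(cfg, tables)
    if ingested.mcod:
        run_lambda(cfg, ingested)
    run_psa(cfg, tables)
    ztests = run_ztest(cfg, ingested)
    run_report(cfg, em_results, ztests)
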
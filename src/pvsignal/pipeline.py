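"""Pipeline orchestration: configuration, stage functions, report assembly.

The pipeline runs read -> dedup/delete -> per-drug cohort -> signals ->
report tables, writing per drug a demographics summary, the full machine
signal table, a top-N-by-ROR presentation table, the SOC distribution,
and per-SOC PT tables, plus a machine-readable run log with row counts at
every stage.  Each stage is also usable standalone on TSV intermediates
(the CLI subcommands), and stage composition is bit-identical to the
end-to-end run.
"""

from __future__ import annotations

import json
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import dedup as dedup_mod
from . import faers_io
from .cohort import DrugQuery, build_cohort, summarize_demographics
from .dedup import AnalysisSet, build_analysis_set
from .faers_io import FormatError, RawQuarter, read_quarter, write_table
from .signals import (
    PtSocMap,
    Thresholds,
    build_tables,
    evaluate_signals,
    flagged,
    pt_distribution_within_soc,
    rank_signals,
    results_to_frame,
    soc_distribution,
)

_DEMO_FILE_RE = re.compile(r"^DEMO(\d{2})Q([1-4])\.txt$", re.IGNORECASE)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Declarative run configuration (one YAML file captures a whole run)."""

    quarters_dir: Path
    drugs: list[DrugQuery]
    output_dir: Path
    pt_soc_map: Path | None = None
    match_mode: str = "substring"
    method: str = "combined"
    rank_by: str = "ror"
    top_n: int = 20
    counting_unit: str = "pair"
    thresholds: Thresholds = field(default_factory=Thresholds)
    precision: int = 2
    top_countries: int = 5
    n_soc_detail: int = 3

    def __post_init__(self):
        if not self.drugs:
            raise ConfigError("config lists no drugs")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, base=Path(path).parent)

    @classmethod
    def from_dict(cls, data: dict, base: Path = Path(".")) -> "PipelineConfig":
        def _path(key, required=True):
            if key not in data or data[key] is None:
                if required:
                    raise ConfigError(f"config key {key!r} is required")
                return None
            p = Path(data[key])
            return p if p.is_absolute() else base / p

        drugs_raw = data.get("drugs") or []
        drugs = [DrugQuery(d["label"], tuple(d["patterns"])) for d in drugs_raw]
        thr = Thresholds(**data.get("thresholds", {}))
        return cls(
            quarters_dir=_path("quarters_dir"),
            drugs=drugs,
            output_dir=_path("output_dir"),
            pt_soc_map=_path("pt_soc_map", required=False),
            match_mode=data.get("match_mode", "substring"),
            method=data.get("method", "combined"),
            rank_by=data.get("rank_by", "ror"),
            top_n=int(data.get("top_n", 20)),
            counting_unit=data.get("counting_unit", "pair"),
            thresholds=thr,
            precision=int(data.get("precision", 2)),
            top_countries=int(data.get("top_countries", 5)),
            n_soc_detail=int(data.get("n_soc_detail", 3)),
        )


def discover_quarters(quarters_dir: Path | str) -> list[tuple[str, dict[str, Path]]]:
    """Find quarterly table files (DEMOyyQq.txt etc.) under a directory.

    Returns ``(quarter_id, paths)`` pairs sorted by quarter; a shared
    DELETED.txt, when present, is attached to every quarter.
    """
    qdir = Path(quarters_dir)
    found = []
    deleted = None
    for cand in ("DELETED.txt", "deleted.txt"):
        if (qdir / cand).exists():
            deleted = qdir / cand
            break
    for path in sorted(qdir.iterdir()):
        m = _DEMO_FILE_RE.match(path.name)
        if not m:
            continue
        yy, q = m.group(1), m.group(2)
        quarter_id = f"{2000 + int(yy)}q{q}"
        suffix = path.name[4:]
        paths: dict[str, Path] = {"demo": path}
        for table in ("drug", "reac", "ther", "indi"):
            cand = qdir / f"{table.upper()}{suffix}"
            if cand.exists():
                paths[table] = cand
        if deleted is not None:
            paths["deleted"] = deleted
        found.append((quarter_id, paths))
    if not found:
        raise FormatError(f"no DEMOyyQq.txt files found under {qdir}")
    return sorted(found)


def load_quarters(quarters_dir: Path | str) -> list[RawQuarter]:
    return [read_quarter(paths, qid) for qid, paths in discover_quarters(quarters_dir)]


# ---------------------------------------------------------------------------
# intermediate TSV stage I/O (lossless, machine precision)
# ---------------------------------------------------------------------------

_INTERMEDIATE = {"reports": "reports.tsv", "drugs": "drugs.tsv", "events": "events.tsv"}


def write_analysis_set(aset: AnalysisSet, out_dir: Path | str) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aset.reports.to_csv(out / _INTERMEDIATE["reports"], sep="\t", index=False)
    aset.drugs.to_csv(out / _INTERMEDIATE["drugs"], sep="\t", index=False)
    aset.events.to_csv(out / _INTERMEDIATE["events"], sep="\t", index=False)
    with open(out / "stage_log.json", "w", encoding="utf-8") as fh:
        json.dump(aset.log, fh, indent=2, sort_keys=True)


def read_analysis_set(in_dir: Path | str) -> AnalysisSet:
    ind = Path(in_dir)
    for name in _INTERMEDIATE.values():
        if not (ind / name).exists():
            raise FormatError(
                f"{ind / name} not found: run the 'dedup' subcommand first"
            )
    reports = pd.read_csv(
        ind / _INTERMEDIATE["reports"],
        sep="\t",
        dtype={"sex": str, "occp_cod": str, "reporter_country": str, "quarter": str},
        keep_default_na=False,
        na_values=[""],
    )
    reports["occp_cod"] = reports["occp_cod"].fillna("")
    reports["reporter_country"] = reports["reporter_country"].fillna("")
    drugs = pd.read_csv(
        ind / _INTERMEDIATE["drugs"],
        sep="\t",
        dtype={"role_cod": str, "drugname": str, "prod_ai": str},
        keep_default_na=False,
        na_values=[""],
    )
    drugs["drugname"] = drugs["drugname"].fillna("")
    drugs["prod_ai"] = drugs["prod_ai"].fillna("")
    events = pd.read_csv(ind / _INTERMEDIATE["events"], sep="\t", dtype={"pt": str})
    log = {}
    log_path = ind / "stage_log.json"
    if log_path.exists():
        with open(log_path, "r", encoding="utf-8") as fh:
            log = json.load(fh)
    return AnalysisSet(reports=reports, drugs=drugs, events=events, log=log)


# ---------------------------------------------------------------------------
# per-drug analysis
# ---------------------------------------------------------------------------


@dataclass
class DrugAnalysis:
    query: DrugQuery
    cohort_ids: set[int]
    results: list  # SignalResult
    demographics: object  # DemographicSummary


def analyze_drug(
    aset: AnalysisSet,
    query: DrugQuery,
    soc_map: PtSocMap | None,
    config: PipelineConfig,
) -> DrugAnalysis:
    cohort_ids = build_cohort(aset.reports, aset.drugs, query, mode=config.match_mode)
    cohort_reports = aset.reports[aset.reports["primaryid"].isin(cohort_ids)]
    demographics = summarize_demographics(cohort_reports)
    tables = build_tables(
        cohort_ids,
        aset.events,
        aset.reports["primaryid"].to_numpy(),
        unit=config.counting_unit,
    )
    results = evaluate_signals(query.label, tables, soc_map, config.thresholds)
    return DrugAnalysis(
        query=query, cohort_ids=cohort_ids, results=results, demographics=demographics
    )


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


def write_drug_outputs(
    analysis: DrugAnalysis, out_dir: Path, config: PipelineConfig
) -> dict:
    """Write all report tables for one drug; returns stage counts."""
    label = _slug(analysis.query.label)
    write_table(
        analysis.demographics.to_frame(),
        out_dir / f"{label}_demographics.tsv",
        precision=config.precision,
    )
    frame = results_to_frame(analysis.results)
    write_table(frame, out_dir / f"{label}_signals.tsv", precision=None)
    top = rank_signals(
        analysis.results, by=config.rank_by, top_n=config.top_n, method=config.method
    )
    write_table(
        results_to_frame(top),
        out_dir / f"{label}_top{config.top_n}.tsv",
        precision=config.precision,
        columns=[
            "drug",
            "pt",
            "soc",
            "a",
            "ror",
            "ror_ci95_low",
            "ror_ci95_high",
            "prr",
            "chi2",
        ],
    )
    dist = soc_distribution(analysis.results, method=config.method)
    write_table(
        dist.table, out_dir / f"{label}_soc_distribution.tsv", precision=config.precision
    )
    for soc in dist.table["soc"].head(config.n_soc_detail):
        subset = pt_distribution_within_soc(
            analysis.results, soc, method=config.method, by=config.rank_by
        )
        write_table(
            results_to_frame(subset),
            out_dir / f"{label}_soc_{_slug(soc)}_pts.tsv",
            precision=config.precision,
            columns=["drug", "pt", "soc", "a", "ror", "prr", "chi2"],
        )
    n_flagged = len(flagged(analysis.results, config.method))
    return {
        "cohort_size": len(analysis.cohort_ids),
        "pts_observed": len(analysis.results),
        "signals_flagged": n_flagged,
        "n_socs": dist.n_socs,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """End-to-end run; outputs appear atomically in ``config.output_dir``.

    Tables are assembled in a scratch subdirectory and moved into place
    only on success, so a failed stage leaves no partial outputs behind.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    staging = out / "_partial"
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir()
    try:
        quarters = load_quarters(config.quarters_dir)
        aset = build_analysis_set(quarters)
        soc_map = (
            PtSocMap.from_tsv(config.pt_soc_map) if config.pt_soc_map is not None else None
        )
        write_analysis_set(aset, staging)
        run_log = {"stages": aset.log, "drugs": {}}
        for query in config.drugs:
            analysis = analyze_drug(aset, query, soc_map, config)
            run_log["drugs"][query.label] = write_drug_outputs(analysis, staging, config)
        with open(staging / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
    except Exception:
        shutil.rmtree(staging, ignore_errors=True)
        raise
    for child in sorted(staging.iterdir()):
        target = out / child.name
        if target.exists():
            target.unlink()
        child.rename(target)
    staging.rmdir()
    return out
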
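"""Reading and writing FAERS-style quarterly ASCII tables.

FAERS public extracts are ``$``-delimited text files, one per table per
quarter (DEMO, DRUG, REAC, THER, INDI) plus a list of deleted case ids.
This module parses that dialect into typed :class:`pandas.DataFrame`
objects with a fixed internal schema, tallying every rejected row so that
``accepted + rejected == physical rows`` holds for each file.

The dialect has no quoting: an embedded ``$`` cannot occur, so a row whose
field count disagrees with the header is corrupt and is rejected rather
than repaired.  Only the post-2012 PRIMARYID-keyed format is supported.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DELIMITER = "$"

#: header-name variants seen across FAERS quarters, mapped to canonical names
HEADER_ALIASES = {"GNDR_COD": "SEX"}

#: mandatory columns per table (after alias resolution)
MANDATORY_COLUMNS = {
    "demo": (
        "PRIMARYID",
        "CASEID",
        "FDA_DT",
        "SEX",
        "AGE",
        "AGE_COD",
        "OCCP_COD",
        "REPORTER_COUNTRY",
    ),
    "drug": ("PRIMARYID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME", "PROD_AI"),
    "reac": ("PRIMARYID", "PT"),
    "ther": ("PRIMARYID",),
    "indi": ("PRIMARYID",),
}

#: FAERS AGE_COD units -> multiplicative factor to years (8766 h per year)
AGE_CODE_FACTORS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.14,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_YEARS_MAX = 130.0

#: DRUG.ROLE_COD values: primary suspect, secondary suspect, concomitant, interacting
ROLE_CODES = ("PS", "SS", "C", "I")

_QUARTER_RE = re.compile(r"^(\d{4})q([1-4])$")


class FormatError(RuntimeError):
    """A file violates the FAERS ASCII format in a non-recoverable way."""


def parse_quarter_id(quarter_id: str) -> tuple[int, int]:
    """Validate ``YYYYqN`` and return ``(year, quarter)``."""
    m = _QUARTER_RE.match(quarter_id)
    if not m:
        raise FormatError(f"bad quarter id {quarter_id!r}: expected 'YYYYqN'")
    year, q = int(m.group(1)), int(m.group(2))
    if not 1990 <= year <= 2100:
        raise FormatError(f"bad quarter id {quarter_id!r}: year out of range")
    return year, q


# ---------------------------------------------------------------------------
# record-level domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class CaseReport:
    """One deduplicated safety report.

    ``sex`` is ``'M'``/``'F'``/``'U'``; ``age_years`` is NaN when unknown;
    ``occp_cod`` is the raw FAERS occupation code (empty when missing);
    ``country`` is the reporter country (empty when missing).
    """

    primary_id: int
    case_id: int
    fda_date: int  # YYYYMMDD, -1 when unparseable
    sex: str
    age_years: float
    occp_cod: str
    country: str
    quarter_id: str


@dataclass(frozen=True, slots=True)
class DrugMention:
    """A drug row tied to a report; ``role`` is one of PS/SS/C/I."""

    primary_id: int
    drug_seq: int
    role: str
    verbatim_name: str
    active_ingredient: str


@dataclass(frozen=True, slots=True)
class EventMention:
    """A (report, MedDRA preferred term) pair, PT in canonical case."""

    primary_id: int
    pt: str


# ---------------------------------------------------------------------------
# normalization helpers
# ---------------------------------------------------------------------------


def normalize_age(age_value: float, age_code: str) -> float:
    """Convert a FAERS (AGE, AGE_COD) pair to years.

    Total function: anything unparseable, a missing unit code, or a result
    outside [0, 130] maps to NaN rather than raising.
    """
    try:
        value = float(age_value)
    except (TypeError, ValueError):
        return float("nan")
    if not np.isfinite(value):
        return float("nan")
    code = str(age_code).strip().upper() if age_code is not None else ""
    factor = AGE_CODE_FACTORS.get(code)
    if factor is None:
        return float("nan")
    years = value * factor
    if not 0.0 <= years <= AGE_YEARS_MAX:
        return float("nan")
    return years


def normalize_age_series(values: pd.Series, codes: pd.Series) -> pd.Series:
    """Vectorised :func:`normalize_age` over aligned Series."""
    value = pd.to_numeric(values, errors="coerce")
    factor = codes.fillna("").astype(str).str.strip().str.upper().map(AGE_CODE_FACTORS)
    years = value * factor
    years[(years < 0.0) | (years > AGE_YEARS_MAX)] = np.nan
    return years.astype(float)


def normalize_pt(pt: str) -> str:
    """Trim, collapse whitespace, and case-fold a PT to MedDRA-style
    capitalization (first letter upper, remainder lower)."""
    s = re.sub(r"\s+", " ", str(pt).strip()).lower()
    return s[:1].upper() + s[1:]


def normalize_pt_series(pts: pd.Series) -> pd.Series:
    s = (
        pts.fillna("")
        .astype(str)
        .str.strip()
        .str.replace(r"\s+", " ", regex=True)
        .str.lower()
    )
    return s.str.slice(0, 1).str.upper() + s.str.slice(1)


# ---------------------------------------------------------------------------
# quarter reading
# ---------------------------------------------------------------------------


@dataclass
class RawQuarter:
    """Parsed tables of one FAERS quarter plus per-table audit tallies.

    ``rejects[table][reason]`` counts rows excluded from the frames;
    ``warnings`` counts recoverable oddities (e.g. unparseable dates kept
    with ``fda_dt == -1``).  ``row_counts[table]`` is the physical data row
    count, so ``len(frame) + sum(rejects[table].values()) == row_counts[table]``.
    """

    quarter_id: str
    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    indi: pd.DataFrame
    deleted_case_ids: set[int] = field(default_factory=set)
    rejects: dict[str, dict[str, int]] = field(default_factory=dict)
    warnings: dict[str, dict[str, int]] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)


def _split_rows(path: Path, table: str) -> tuple[list[str], list[list[str]], int]:
    """Read a '$'-delimited file; return (header, well-shaped rows, bad-shape count)."""
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].strip():
        raise FormatError(f"{path}: empty file")
    header = [HEADER_ALIASES.get(h.strip().upper(), h.strip().upper()) for h in lines[0].split(DELIMITER)]
    for col in MANDATORY_COLUMNS[table]:
        if col not in header:
            raise FormatError(f"{path}: missing mandatory column {col}")
    ncol = len(header)
    rows: list[list[str]] = []
    bad_shape = 0
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.split(DELIMITER)
        if len(fields) != ncol:
            bad_shape += 1
            continue
        rows.append(fields)
    return header, rows, bad_shape


def _read_table(path: Path, table: str) -> tuple[pd.DataFrame, dict[str, int], int]:
    header, rows, bad_shape = _split_rows(Path(path), table)
    rejects = {"field_count": bad_shape} if bad_shape else {}
    raw = pd.DataFrame(rows, columns=header, dtype=str)
    raw = raw[list(MANDATORY_COLUMNS[table])]
    pid = pd.to_numeric(raw["PRIMARYID"].str.strip(), errors="coerce")
    bad_pid = int(pid.isna().sum())
    if bad_pid:
        rejects["bad_primaryid"] = bad_pid
    raw = raw[pid.notna()].copy()
    raw["PRIMARYID"] = pid[pid.notna()].astype(np.int64)
    n_physical = len(rows) + bad_shape
    return raw, rejects, n_physical


def _postprocess_demo(
    raw: pd.DataFrame, quarter_id: str
) -> tuple[pd.DataFrame, dict[str, int], dict[str, int]]:
    rejects: dict[str, int] = {}
    warnings: dict[str, int] = {}
    cid = pd.to_numeric(raw["CASEID"].str.strip(), errors="coerce")
    bad_cid = int(cid.isna().sum())
    if bad_cid:
        rejects["bad_caseid"] = bad_cid
    out = raw[cid.notna()].copy()
    out["CASEID"] = cid[cid.notna()].astype(np.int64)

    fda = pd.to_numeric(out["FDA_DT"].str.strip(), errors="coerce")
    bad_date = fda.isna() | (fda < 19000101) | (fda > 21001231)
    n_bad_date = int(bad_date.sum())
    if n_bad_date:
        warnings["bad_fda_dt"] = n_bad_date
    fda = fda.where(~bad_date, -1).astype(np.int64)

    sex = out["SEX"].str.strip().str.upper()
    sex = sex.where(sex.isin(["M", "F"]), "U")

    age_years = normalize_age_series(out["AGE"], out["AGE_COD"])
    n_age_dropped = int(
        (pd.to_numeric(out["AGE"], errors="coerce").notna() & age_years.isna()).sum()
    )
    if n_age_dropped:
        warnings["age_unusable"] = n_age_dropped

    frame = pd.DataFrame(
        {
            "primaryid": out["PRIMARYID"].to_numpy(),
            "caseid": out["CASEID"].to_numpy(),
            "fda_dt": fda.to_numpy(),
            "sex": sex.to_numpy(),
            "age_years": age_years.to_numpy(),
            "occp_cod": out["OCCP_COD"].str.strip().str.upper().to_numpy(),
            "reporter_country": out["REPORTER_COUNTRY"].str.strip().str.upper().to_numpy(),
            "quarter": quarter_id,
        }
    )
    return frame, rejects, warnings


def _postprocess_drug(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    rejects: dict[str, int] = {}
    role = raw["ROLE_COD"].str.strip().str.upper()
    bad_role = ~role.isin(ROLE_CODES)
    if bad_role.any():
        rejects["bad_role_cod"] = int(bad_role.sum())
    out = raw[~bad_role]
    seq = pd.to_numeric(out["DRUG_SEQ"].str.strip(), errors="coerce").fillna(0)
    frame = pd.DataFrame(
        {
            "primaryid": out["PRIMARYID"].to_numpy(),
            "drug_seq": seq.astype(np.int64).to_numpy(),
            "role_cod": role[~bad_role].to_numpy(),
            "drugname": out["DRUGNAME"].str.strip().to_numpy(),
            "prod_ai": out["PROD_AI"].str.strip().to_numpy(),
        }
    )
    return frame, rejects


def _postprocess_reac(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    rejects: dict[str, int] = {}
    pt = normalize_pt_series(raw["PT"])
    empty = pt.str.len() == 0
    if empty.any():
        rejects["empty_pt"] = int(empty.sum())
    frame = pd.DataFrame(
        {
            "primaryid": raw.loc[~empty, "PRIMARYID"].to_numpy(),
            "pt": pt[~empty].to_numpy(),
        }
    )
    return frame, rejects


def read_deleted_list(path: Path) -> tuple[set[int], int]:
    """Read a one-CASEID-per-line deletion list; returns (ids, bad-line count)."""
    ids: set[int] = set()
    bad = 0
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for line in fh:
            s = line.strip()
            if not s or s.upper() == "CASEID":
                continue
            try:
                ids.add(int(s))
            except ValueError:
                bad += 1
    return ids, bad


def read_quarter(paths: Mapping[str, Path | str], quarter_id: str) -> RawQuarter:
    """Read one quarter's tables into a :class:`RawQuarter`.

    ``paths`` must contain ``demo``, ``drug`` and ``reac``; ``ther``,
    ``indi`` and ``deleted`` are optional.  Malformed rows are excluded and
    tallied per table in ``rejects``; a missing mandatory column or an
    empty file raises :class:`FormatError`.
    """
    parse_quarter_id(quarter_id)
    for key in ("demo", "drug", "reac"):
        if key not in paths:
            raise FormatError(f"quarter {quarter_id}: no path given for table {key!r}")

    rejects: dict[str, dict[str, int]] = {}
    warnings: dict[str, dict[str, int]] = {}
    row_counts: dict[str, int] = {}

    raw_demo, rej, row_counts["demo"] = _read_table(Path(paths["demo"]), "demo")
    demo, rej2, warn = _postprocess_demo(raw_demo, quarter_id)
    rejects["demo"] = {**rej, **rej2}
    warnings["demo"] = warn

    raw_drug, rej, row_counts["drug"] = _read_table(Path(paths["drug"]), "drug")
    drug, rej2 = _postprocess_drug(raw_drug)
    rejects["drug"] = {**rej, **rej2}

    raw_reac, rej, row_counts["reac"] = _read_table(Path(paths["reac"]), "reac")
    reac, rej2 = _postprocess_reac(raw_reac)
    rejects["reac"] = {**rej, **rej2}

    ther = pd.DataFrame(columns=["primaryid"])
    indi = pd.DataFrame(columns=["primaryid"])
    for key, target in (("ther", "ther"), ("indi", "indi")):
        if key in paths and paths[key] is not None:
            raw, rej, row_counts[key] = _read_table(Path(paths[key]), target)
            frame = pd.DataFrame({"primaryid": raw["PRIMARYID"].to_numpy()})
            rejects[key] = rej
            if key == "ther":
                ther = frame
            else:
                indi = frame

    deleted: set[int] = set()
    if "deleted" in paths and paths["deleted"] is not None:
        deleted, bad = read_deleted_list(Path(paths["deleted"]))
        if bad:
            warnings["deleted"] = {"bad_line": bad}

    return RawQuarter(
        quarter_id=quarter_id,
        demo=demo,
        drug=drug,
        reac=reac,
        ther=ther,
        indi=indi,
        deleted_case_ids=deleted,
        rejects=rejects,
        warnings=warnings,
        row_counts=row_counts,
    )


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


@dataclass
class PooledQuarters:
    """Concatenated tables of several quarters, with orphan-row audit.

    Orphan DRUG/REAC rows (report id absent from every loaded DEMO) are
    counted in ``orphan_counts`` but kept in the frames: dropping them is a
    deduplication concern, not a parsing one.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    deleted_case_ids: set[int]
    orphan_counts: dict[str, int]
    rejects: dict[str, dict[str, dict[str, int]]]
    row_counts: dict[str, dict[str, int]]


def pool_quarters(quarters: Sequence[RawQuarter]) -> PooledQuarters:
    if not quarters:
        raise ValueError("no quarters to pool")
    demo = pd.concat([q.demo for q in quarters], ignore_index=True)
    drug = pd.concat([q.drug for q in quarters], ignore_index=True)
    reac = pd.concat([q.reac for q in quarters], ignore_index=True)
    deleted = set().union(*(q.deleted_case_ids for q in quarters))
    known = set(demo["primaryid"].to_numpy())
    orphans = {
        "drug": int((~drug["primaryid"].isin(known)).sum()),
        "reac": int((~reac["primaryid"].isin(known)).sum()),
    }
    return PooledQuarters(
        demo=demo,
        drug=drug,
        reac=reac,
        deleted_case_ids=deleted,
        orphan_counts=orphans,
        rejects={q.quarter_id: q.rejects for q in quarters},
        row_counts={q.quarter_id: q.row_counts for q in quarters},
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_table(
    rows,
    path: Path | str,
    fmt: str = "tsv",
    precision: int = 2,
    columns: Sequence[str] | None = None,
) -> None:
    """Write results as TSV/CSV with deterministic column order.

    ``rows`` may be a DataFrame or an iterable of dataclasses / mappings.
    Floats are rendered at fixed ``precision``; pass ``precision=None`` for
    lossless full-repr output (machine tables).  An empty collection with
    ``columns`` yields a header-only file.
    """
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        records = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in rows
        ]
        frame = pd.DataFrame(records, columns=columns if not records else None)
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    float_format = None if precision is None else f"%.{precision}f"
    try:
        frame.to_csv(path, sep=sep, index=False, float_format=float_format)
    except OSError as exc:
        raise FormatError(f"cannot write {path}: {exc}") from exc


def read_table(path: Path | str, fmt: str = "tsv") -> pd.DataFrame:
    sep = "\t" if fmt == "tsv" else ","
    return pd.read_csv(path, sep=sep)
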
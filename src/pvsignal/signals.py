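"""Disproportionality statistics on drug / adverse-event fourfold tables.

For one target drug and one MedDRA preferred term (PT), reports are
cross-classified against the background of all other reports:

========================  ==============  ===============
                          target PT       all other PTs
========================  ==============  ===============
target drug               a               b
all other drugs           c               d
========================  ==============  ===============

The counting unit is the unique (report, PT) pair, so ``a + b`` is the
cohort's total pair count for every PT of a given drug (a report-level
unit is available as a switch).  Two classical signal criteria are
computed:

* reporting odds ratio, ``ROR = (a/c)/(b/d) = ad/bc``, with a log-normal
  Wald 95% interval ``exp(ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d))``;
  a signal requires ``a >= 3`` and a CI lower bound strictly above 1;
* the MHRA criterion, ``PRR = [a/(a+b)] / [c/(c+d)]`` with the Pearson
  chi-square (no continuity correction by default); a signal requires
  ``a >= 3``, ``PRR >= 2`` and ``chi2 >= 4``.

The combined flag is the conjunction of the two, the conservative reading
of applying both methods to suppress false positives.  Tables with a zero
cell are marked non-computable (no Haldane-Anscombe correction) and never
flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .faers_io import normalize_pt

UNMAPPED_SOC = "UNMAPPED"

COUNTING_UNITS = ("pair", "report")


class ZeroCellError(ValueError):
    """A margin or cell needed by the statistic is zero."""


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Fourfold counts for one (drug, PT); all cells non-negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class Thresholds:
    """Signal thresholds: a>=min_a, CI low > ci_low_gt, PRR>=min_prr, chi2>=min_chi2."""

    min_a: int = 3
    ci_low_gt: float = 1.0
    min_prr: float = 2.0
    min_chi2: float = 4.0
    z: float = 1.96
    yates: bool = False


@dataclass(frozen=True, slots=True)
class SignalStats:
    """ROR/PRR/chi-square values and threshold flags for one table.

    Non-computable tables (zero cell or margin) carry NaN statistics, a
    ``reason`` code, and all flags false.
    """

    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    computable: bool = True
    reason: str | None = None
    ror_flag: bool = False
    mhra_flag: bool = False
    combined_flag: bool = False


@dataclass(frozen=True, slots=True)
class SignalResult:
    drug_label: str
    pt: str
    soc: str | None
    table: ContingencyTable
    stats: SignalStats


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def ror_with_ci(t: ContingencyTable, z: float = 1.96) -> tuple[float, float, float]:
    """Reporting odds ratio with log-normal Wald CI.

    Raises :class:`ZeroCellError` on any zero cell; no continuity
    correction is applied.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        raise ZeroCellError("zero cell in fourfold table")
    ror = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    log_ror = math.log(ror)
    return ror, math.exp(log_ror - z * se), math.exp(log_ror + z * se)


def prr_chi2(t: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-square.

    ``chi2 = (ad - bc)^2 N / [(a+b)(c+d)(a+c)(b+d)]``, uncorrected unless
    ``yates``; PRR needs ``c > 0`` and both row margins positive.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if min(row1, row2, col1, col2) == 0:
        raise ZeroCellError("zero margin in fourfold table")
    if c == 0 or a == 0:
        raise ZeroCellError("zero cell in first column")
    prr = (a * row2) / (row1 * c)
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    chi2 = (diff * diff) * n / (row1 * row2 * col1 * col2)
    return prr, chi2


def flag_signal(stats: SignalStats, t: ContingencyTable, thresholds: Thresholds = Thresholds()) -> SignalStats:
    """Set the ROR, MHRA and combined flags from the printed inequalities."""
    if not stats.computable:
        return replace(stats, ror_flag=False, mhra_flag=False, combined_flag=False)
    ror_flag = t.a >= thresholds.min_a and stats.ror_ci_low > thresholds.ci_low_gt
    mhra_flag = (
        t.a >= thresholds.min_a
        and stats.prr >= thresholds.min_prr
        and stats.chi2 >= thresholds.min_chi2
    )
    return replace(
        stats,
        ror_flag=ror_flag,
        mhra_flag=mhra_flag,
        combined_flag=ror_flag and mhra_flag,
    )


def compute_stats(t: ContingencyTable, thresholds: Thresholds = Thresholds()) -> SignalStats:
    """ROR, CI, PRR and chi-square for one table, with flags set."""
    nan = float("nan")
    try:
        ror, lo, hi = ror_with_ci(t, z=thresholds.z)
        prr, chi2 = prr_chi2(t, yates=thresholds.yates)
    except ZeroCellError as exc:
        return SignalStats(nan, nan, nan, nan, nan, computable=False, reason=str(exc))
    stats = SignalStats(ror=ror, ror_ci_low=lo, ror_ci_high=hi, prr=prr, chi2=chi2)
    return flag_signal(stats, t, thresholds)


# ---------------------------------------------------------------------------
# table construction
# ---------------------------------------------------------------------------


def build_tables(
    cohort_ids: Iterable[int],
    all_events: pd.DataFrame,
    all_report_ids: Iterable[int],
    unit: str = "pair",
) -> dict[str, ContingencyTable]:
    """Fourfold tables for every PT observed in the cohort.

    ``all_events`` must hold unique (primaryid, pt) pairs over the full
    deduplicated report set.  With ``unit='pair'`` the cell totals are
    pair counts (``a+b`` constant per drug); with ``unit='report'`` they
    are report counts (``b`` = cohort reports without the PT).
    """
    if unit not in COUNTING_UNITS:
        raise ValueError(f"unknown counting unit {unit!r}")
    cohort = set(cohort_ids)
    universe = set(all_report_ids)
    if not cohort:
        return {}
    if not cohort <= universe:
        raise ValueError("cohort ids not a subset of the report universe")
    ev = all_events[all_events["primaryid"].isin(universe)]
    in_cohort = ev["primaryid"].isin(cohort).to_numpy()
    a_counts = ev.loc[in_cohort, "pt"].value_counts()
    c_counts = ev.loc[~in_cohort, "pt"].value_counts()
    if unit == "pair":
        total_a = int(in_cohort.sum())
        total_c = int(len(ev) - total_a)
    else:
        total_a = len(cohort)
        total_c = len(universe) - len(cohort)
    tables: dict[str, ContingencyTable] = {}
    for pt, a in a_counts.items():
        a = int(a)
        c = int(c_counts.get(pt, 0))
        tables[pt] = ContingencyTable(a=a, b=total_a - a, c=c, d=total_c - c)
    return tables


# ---------------------------------------------------------------------------
# MedDRA PT -> SOC mapping
# ---------------------------------------------------------------------------


class PtSocMap:
    """Many-to-one preferred-term to System Organ Class mapping.

    Built from a user-supplied two-column TSV (the licensed MedDRA
    dictionary cannot be redistributed); PT keys are normalized to
    canonical case, and duplicate keys after normalization are an error.
    """

    def __init__(self, entries: Mapping[str, str]):
        norm: dict[str, str] = {}
        for pt, soc in entries.items():
            key = normalize_pt(pt)
            if key in norm and norm[key] != str(soc).strip():
                raise ValueError(f"conflicting SOC for PT {key!r}")
            norm[key] = str(soc).strip()
        self._entries = norm

    @classmethod
    def from_tsv(cls, path: Path | str) -> "PtSocMap":
        frame = pd.read_csv(path, sep="\t", header=None, names=["pt", "soc"], dtype=str)
        if not frame.empty and frame.iloc[0]["pt"].strip().lower() == "pt":
            frame = frame.iloc[1:]
        return cls(dict(zip(frame["pt"], frame["soc"])))

    def get(self, pt: str) -> str | None:
        return self._entries.get(normalize_pt(pt))

    def __contains__(self, pt: str) -> bool:
        return normalize_pt(pt) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def socs(self) -> set[str]:
        return set(self._entries.values())


# ---------------------------------------------------------------------------
# evaluation, ranking, SOC aggregation
# ---------------------------------------------------------------------------


def evaluate_signals(
    drug_label: str,
    tables: Mapping[str, ContingencyTable],
    soc_map: PtSocMap | None = None,
    thresholds: Thresholds = Thresholds(),
) -> list[SignalResult]:
    """Compute stats and flags for every PT table of one drug.

    PTs absent from the SOC map get ``soc=None`` (they aggregate under
    ``UNMAPPED`` downstream).  Results are returned in deterministic PT
    order.
    """
    results = []
    for pt in sorted(tables):
        t = tables[pt]
        soc = soc_map.get(pt) if soc_map is not None else None
        results.append(
            SignalResult(
                drug_label=drug_label,
                pt=pt,
                soc=soc,
                table=t,
                stats=compute_stats(t, thresholds),
            )
        )
    return results


def _flag_of(result: SignalResult, method: str) -> bool:
    if method == "combined":
        return result.stats.combined_flag
    if method == "ror":
        return result.stats.ror_flag
    if method == "mhra":
        return result.stats.mhra_flag
    raise ValueError(f"unknown method {method!r}")


def flagged(results: Iterable[SignalResult], method: str = "combined") -> list[SignalResult]:
    return [r for r in results if _flag_of(r, method)]


def rank_signals(
    results: Iterable[SignalResult],
    by: str = "ror",
    top_n: int | None = None,
    method: str = "combined",
) -> list[SignalResult]:
    """Flagged signals in stable descending order.

    Key is ROR or case count ``a``; ties break by ``a`` descending, then
    PT alphabetical.  ``top_n`` larger than the result set returns all.
    """
    if by not in ("ror", "case_count"):
        raise ValueError(f"unknown ranking key {by!r}")
    keep = flagged(results, method)

    def key(r: SignalResult):
        primary = r.stats.ror if by == "ror" else r.table.a
        return (-primary, -r.table.a, r.pt)

    ordered = sorted(keep, key=key)
    return ordered if top_n is None else ordered[:top_n]


@dataclass
class SocDistribution:
    """Case-count share of each SOC among one drug's flagged signals."""

    table: pd.DataFrame  # columns: soc, n_signal_pts, case_count, pct
    n_socs: int
    n_unmapped_pts: int


def soc_distribution(
    results: Iterable[SignalResult],
    soc_map: PtSocMap | None = None,
    method: str = "combined",
) -> SocDistribution:
    """Aggregate flagged signals of one drug by System Organ Class.

    The percentage is the SOC's share of case counts: sum of ``a`` over
    the SOC's signal PTs divided by the sum over all signal PTs, x100.
    Unmapped PTs accumulate under the reserved ``UNMAPPED`` SOC.
    """
    keep = flagged(results, method)
    rows: dict[str, list[int]] = {}
    n_unmapped = 0
    for r in keep:
        soc = r.soc or (soc_map.get(r.pt) if soc_map is not None else None)
        if soc is None:
            soc = UNMAPPED_SOC
            n_unmapped += 1
        acc = rows.setdefault(soc, [0, 0])
        acc[0] += 1
        acc[1] += r.table.a
    total_cases = sum(v[1] for v in rows.values())
    records = [
        (
            soc,
            n_pts,
            cases,
            100.0 * cases / total_cases if total_cases else float("nan"),
        )
        for soc, (n_pts, cases) in rows.items()
    ]
    frame = pd.DataFrame(
        records, columns=["soc", "n_signal_pts", "case_count", "pct"]
    ).sort_values(["case_count", "soc"], ascending=[False, True], kind="mergesort")
    n_socs = len([s for s in rows if s != UNMAPPED_SOC])
    return SocDistribution(table=frame.reset_index(drop=True), n_socs=n_socs, n_unmapped_pts=n_unmapped)


def pt_distribution_within_soc(
    results: Iterable[SignalResult],
    soc: str,
    soc_map: PtSocMap | None = None,
    method: str = "combined",
    by: str = "ror",
) -> list[SignalResult]:
    """Flagged signals whose PT maps to ``soc``, ranked like :func:`rank_signals`."""
    subset = []
    for r in results:
        r_soc = r.soc or (soc_map.get(r.pt) if soc_map is not None else None)
        if r_soc == soc:
            subset.append(r)
    return rank_signals(subset, by=by, method=method)


def results_to_frame(results: Iterable[SignalResult]) -> pd.DataFrame:
    """Flat machine-readable table of signal results."""
    rows = []
    for r in results:
        s, t = r.stats, r.table
        rows.append(
            {
                "drug": r.drug_label,
                "pt": r.pt,
                "soc": r.soc if r.soc is not None else UNMAPPED_SOC,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "ror": s.ror,
                "ror_ci95_low": s.ror_ci_low,
                "ror_ci95_high": s.ror_ci_high,
                "prr": s.prr,
                "chi2": s.chi2,
                "ror_flag": s.ror_flag,
                "mhra_flag": s.mhra_flag,
                "combined_flag": s.combined_flag,
            }
        )
    columns = [
        "drug",
        "pt",
        "soc",
        "a",
        "b",
        "c",
        "d",
        "ror",
        "ror_ci95_low",
        "ror_ci95_high",
        "prr",
        "chi2",
        "ror_flag",
        "mhra_flag",
        "combined_flag",
    ]
    return pd.DataFrame(rows, columns=columns)
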
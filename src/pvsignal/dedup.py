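"""Case deduplication and deletion for pooled FAERS quarters.

FAERS re-publishes cases across quarterly extracts, so one CASEID can
carry several PRIMARYID versions.  The rule applied here keeps, per
CASEID, the record with the most recent FDA_DT, breaking date ties by the
higher PRIMARYID; cases listed in the DELETED table are then removed.
Records with an unparseable FDA_DT (stored as -1) lose ties to any record
with a valid date.  Deletion commutes with deduplication, so the order of
the two steps does not affect the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import PooledQuarters, RawQuarter, pool_quarters


def deduplicate(demo: pd.DataFrame) -> pd.DataFrame:
    """Keep one DEMO row per CASEID, maximizing (FDA_DT, PRIMARYID).

    Idempotent; stable with respect to the input order of equally-keyed
    rows because the sort is lexicographic on the full tie-break key.
    """
    ordered = demo.sort_values(["caseid", "fda_dt", "primaryid"], kind="mergesort")
    return ordered.drop_duplicates("caseid", keep="last").reset_index(drop=True)


def apply_deleted(reports: pd.DataFrame, deleted_case_ids: set[int]) -> tuple[pd.DataFrame, int]:
    """Drop reports whose CASEID is on the deletion list.

    Returns the surviving frame and the number of removed reports.  A
    CASEID on the list is removed regardless of which version was deleted.
    """
    if not deleted_case_ids:
        return reports.reset_index(drop=True), 0
    keep = ~reports["caseid"].isin(deleted_case_ids)
    return reports[keep].reset_index(drop=True), int((~keep).sum())


def filter_mentions(mentions: pd.DataFrame, retained_primaryids) -> pd.DataFrame:
    """Restrict DRUG/REAC rows to retained report versions."""
    return mentions[mentions["primaryid"].isin(retained_primaryids)].reset_index(drop=True)


@dataclass
class AnalysisSet:
    """Analysis-ready report set: one row per case, mentions attached.

    ``events`` holds unique (primaryid, pt) pairs — the counting unit of
    the disproportionality analysis.  ``log`` records row counts at every
    stage for the |output| <= |input| audit chain.
    """

    reports: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    log: dict = field(default_factory=dict)


def build_analysis_set(quarters: Sequence[RawQuarter] | PooledQuarters) -> AnalysisSet:
    """Pool quarters, deduplicate, apply deletions, attach mentions."""
    pooled = quarters if isinstance(quarters, PooledQuarters) else pool_quarters(list(quarters))
    n_raw = len(pooled.demo)
    deduped = deduplicate(pooled.demo)
    n_dedup = len(deduped)
    reports, n_deleted = apply_deleted(deduped, pooled.deleted_case_ids)
    retained = set(reports["primaryid"].to_numpy())
    drugs = filter_mentions(pooled.drug, retained)
    events = (
        filter_mentions(pooled.reac, retained)
        .drop_duplicates(["primaryid", "pt"])
        .reset_index(drop=True)
    )
    log = {
        "demo_rows_pooled": n_raw,
        "after_dedup": n_dedup,
        "removed_by_deleted_list": n_deleted,
        "reports_final": len(reports),
        "drug_rows_final": len(drugs),
        "unique_report_pt_pairs": len(events),
        "orphan_rows": pooled.orphan_counts,
        "rejects": pooled.rejects,
        "row_counts": pooled.row_counts,
    }
    return AnalysisSet(reports=reports, drugs=drugs, events=events, log=log)
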
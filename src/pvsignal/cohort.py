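"""Target-drug cohort construction and demographic summaries.

A cohort is the set of deduplicated reports in which the target drug
appears as the primary suspect (ROLE_COD ``PS``).  Drug matching works on
normalized names (uppercased, trimmed, internal whitespace collapsed)
against both the verbatim DRUGNAME and the active ingredient (PROD_AI),
with a word-boundary substring mode by default so that
``TUCATINIB 150MG`` matches the pattern ``TUCATINIB`` while ``ABCTUCATINIBX``
does not.  Exact-match mode reproduces a strict generic-name query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MATCH_MODES = ("substring", "exact")

#: FAERS occupation codes regarded as healthcare professionals
HEALTHCARE_OCCUPATIONS = frozenset({"MD", "PH", "OT", "HP"})
#: consumer / lawyer codes: non-healthcare reporters
NON_HEALTHCARE_OCCUPATIONS = frozenset({"CN", "LW"})

AGE_GROUPS = ("le18", "a18to60", "ge60", "unknown")


def normalize_name(name: str) -> str:
    """Uppercase, trim, and collapse internal whitespace."""
    return re.sub(r"\s+", " ", str(name).strip()).upper()


@dataclass(frozen=True)
class DrugQuery:
    """A target drug: display label plus generic/brand name patterns."""

    label: str
    patterns: tuple[str, ...]

    def __post_init__(self):
        if not self.patterns:
            raise ValueError(f"drug query {self.label!r} has no name patterns")
        object.__setattr__(
            self, "patterns", tuple(normalize_name(p) for p in self.patterns)
        )

    def regex(self) -> str:
        """Word-boundary alternation over all patterns (on normalized names)."""
        alts = "|".join(re.escape(p) for p in self.patterns)
        return rf"(?<![A-Z0-9])(?:{alts})(?![A-Z0-9])"


def match_drug(
    verbatim_name: str,
    active_ingredient: str | None,
    query: DrugQuery,
    mode: str = "substring",
) -> bool:
    """True iff any query pattern matches the drug name or ingredient.

    ``substring`` requires the pattern to occur at word boundaries inside
    the normalized string; ``exact`` requires full-string equality.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {mode!r}")
    targets = [normalize_name(verbatim_name)]
    if active_ingredient:
        targets.append(normalize_name(active_ingredient))
    if mode == "exact":
        return any(t in query.patterns for t in targets)
    rx = re.compile(query.regex())
    return any(rx.search(t) for t in targets)


def build_cohort(
    reports: pd.DataFrame,
    drug_mentions: pd.DataFrame,
    query: DrugQuery,
    mode: str = "substring",
) -> set[int]:
    """Primary ids of reports with the target drug as primary suspect.

    Matching is evaluated over the set of distinct name strings (FAERS
    repeats verbatim names heavily), then mapped back to rows.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {mode!r}")
    ps = drug_mentions[drug_mentions["role_cod"] == "PS"]
    if ps.empty:
        return set()
    names = ps["drugname"].fillna("").astype(str)
    ais = ps["prod_ai"].fillna("").astype(str)

    def _match_unique(series: pd.Series) -> pd.Series:
        uniq = pd.Series(series.unique())
        norm = uniq.map(normalize_name)
        if mode == "exact":
            hit = norm.isin(query.patterns)
        else:
            hit = norm.str.contains(query.regex(), regex=True)
        return series.map(dict(zip(uniq, hit)))

    matched = _match_unique(names) | _match_unique(ais)
    valid = set(reports["primaryid"].to_numpy())
    return set(ps.loc[matched.to_numpy(), "primaryid"].to_numpy()) & valid


def assign_age_group(age_years: float) -> str:
    """Bucket an age: <=18, the open interval (18, 60), >=60, or unknown."""
    if age_years is None or not np.isfinite(age_years):
        return "unknown"
    if age_years <= 18.0:
        return "le18"
    if age_years >= 60.0:
        return "ge60"
    return "a18to60"


def reporter_class(occp_cod: str) -> str:
    code = str(occp_cod).strip().upper()
    if code in HEALTHCARE_OCCUPATIONS:
        return "healthcare"
    if code in NON_HEALTHCARE_OCCUPATIONS:
        return "non_healthcare"
    return "unknown"


@dataclass
class DemographicSummary:
    """Cohort composition: each count family sums to ``n_cases``.

    Percentages are always derived as count / n_cases at presentation
    time, never stored.
    """

    n_cases: int
    sex_counts: dict[str, int]
    age_group_counts: dict[str, int]
    reporter_counts: dict[str, int]
    country_counts: list[tuple[str, int]]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table (section, category, count, percent)."""
        rows = []
        for section, counts in (
            ("sex", self.sex_counts.items()),
            ("age_group", self.age_group_counts.items()),
            ("reporter", self.reporter_counts.items()),
            ("country", self.country_counts),
        ):
            for category, count in counts:
                pct = 100.0 * count / self.n_cases if self.n_cases else float("nan")
                rows.append((section, category, count, pct))
        return pd.DataFrame(rows, columns=["section", "category", "count", "percent"])


def summarize_demographics(
    cohort_reports: pd.DataFrame, top_countries: int | None = None
) -> DemographicSummary:
    """Summarize sex, age group, reporter class and country of a cohort.

    Country ranking is by count descending with alphabetical tie-break;
    missing country strings count under ``unknown``.
    """
    n = len(cohort_reports)
    sex_counts = {
        "male": int((cohort_reports["sex"] == "M").sum()),
        "female": int((cohort_reports["sex"] == "F").sum()),
        "unknown": int((~cohort_reports["sex"].isin(["M", "F"])).sum()),
    }
    groups = cohort_reports["age_years"].map(assign_age_group)
    age_counts = {g: int((groups == g).sum()) for g in AGE_GROUPS}
    classes = cohort_reports["occp_cod"].map(reporter_class)
    rep_counts = {
        c: int((classes == c).sum()) for c in ("healthcare", "non_healthcare", "unknown")
    }
    country = cohort_reports["reporter_country"].fillna("").astype(str).str.strip()
    country = country.where(country != "", "unknown")
    vc = country.value_counts()
    ranked = sorted(vc.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_countries is not None:
        ranked = ranked[:top_countries]
    return DemographicSummary(
        n_cases=n,
        sex_counts=sex_counts,
        age_group_counts=age_counts,
        reporter_counts=rep_counts,
        country_counts=[(c, int(k)) for c, k in ranked],
    )
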
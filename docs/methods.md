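# Methods

## Data model and ingestion

FAERS quarterly extracts are `$`-delimited ASCII tables without quoting.
Because an embedded delimiter cannot occur, a row whose field count
disagrees with the header is treated as corrupt and rejected, never
repaired; every rejection is tallied per table and reason, and the
invariant `accepted + rejected = physical rows` is enforced by test.
Header variants are resolved by a fixed alias map (`GNDR_COD ↔ SEX`).
The legacy pre-2012 ISR-keyed format is out of scope: the pipeline keys
everything on PRIMARYID.

Dates (`FDA_DT`) are parsed as `YYYYMMDD` integers with a plausibility
range check (1900-01-01 to 2100-12-31); an unparseable date is kept as
the sentinel `-1`, which makes the record lose any deduplication tie to
a record with a valid date — a conservative choice, since a dateless
version cannot demonstrate recency.

Ages arrive as (value, unit-code) pairs. The conversion table is the
FAERS convention: `YR` ×1, `DEC` ×10, `MON` ÷12, `WK` ÷52.14, `DY`
÷365.25, `HR` ÷8766. Conversion is a total function: a missing or
unknown unit, a negative value, or a result outside [0, 130] years maps
to missing (tallied), never to an exception. PT strings are trimmed,
whitespace-collapsed and case-folded to MedDRA-style capitalization
(initial capital) before any grouping, because capitalization of the
same term varies across FAERS quarters.

Orphan DRUG/REAC rows (report id absent from every loaded DEMO) are
counted and reported but kept at the parsing layer; they drop out
naturally when mentions are filtered to retained reports.

## Deduplication

One case, one record: per CASEID the record maximizing
(FDA_DT, PRIMARYID) lexicographically is retained, and all drug/event
rows attached to non-retained versions are dropped with their report.
Cases on the DELETED list are removed regardless of which version was
deleted. Deduplication is global across all loaded quarters, since
FAERS re-publishes cases in later quarters. The operation is idempotent
and commutes with deletion; both properties are verified against a
brute-force group-by/sort/max oracle on randomized pools.

## Cohorts and demographics

A report enters a drug's cohort when at least one of its drug mentions
has role code `PS` (primary suspect) and matches the drug query. The
default matching mode is word-boundary substring over the normalized
verbatim name *and* active ingredient, with a synonym list covering
brand names (e.g. TUKYSA for tucatinib): a strict generic-name equality
match would miss salt forms ("LAPATINIB DITOSYLATE") and brand-name
reports. Exact-match mode is available for users who want the stricter
query.

Age groups are ≤18, the open interval (18, 60), and ≥60. The printed
convention in the field overlaps at both boundaries ("≤18", "18–60",
"≥60"); this package resolves the overlap by honoring both inclusive
endpoints, so 18 falls in the youngest group and 60 in the oldest. This
is a genuine free choice — a different assignment moves only
boundary-exact ages between adjacent buckets.

Occupation codes map to reporter classes as `MD, PH, OT, HP` →
healthcare, `CN, LW` → non-healthcare, anything else → unknown. Country
is the reporter country of the retained DEMO record. All percentages
are derived from counts at presentation time; each count family
partitions the cohort exactly.

## Signal statistics

The counting unit is the unique (report, PT) pair: `a + b` is then
constant across PTs of a drug, matching the dominant convention in
FAERS disproportionality work. A report-level unit (`b` = cohort
reports *without* the PT) is available as a configuration switch. The
background is every retained report outside the drug's cohort,
including the cohorts of the other study drugs.

`ROR = ad/bc` with the Wald interval on the log scale (z = 1.96 by
default); `PRR = [a/(a+b)]/[c/(c+d)]`; `χ²` is the uncorrected Pearson
statistic in its cross-product form. A Yates-corrected variant sits
behind a flag for sensitivity analysis but is not the default. Zero
cells are *not* continuity-corrected: the statistics are marked
non-computable with a reason code and the result can never be flagged.
With the `a ≥ 3` signal floor, a corrected `a = 0` estimate could never
change a decision, and correction would silently bias the small tables
it touched.

Threshold semantics: `a ≥ 3`, `PRR ≥ 2`, `χ² ≥ 4` inclusive; CI lower
bound strictly `> 1`. The combined criterion is the conjunction of the
ROR and MHRA criteria — the conservative reading of applying both
methods to minimize false positives — and both per-method flags are
always reported so a union-based reading can be recovered from the
output. Ranking is by descending ROR (or case count), ties broken by
`a` descending then PT alphabetically, so output order is total and
stable.

SOC aggregation reports each SOC's share of *case counts*: the sum of
`a` over the SOC's flagged PTs divided by the sum over all flagged PTs
for the drug. A share of all reported events (flagged or not) would be
an alternative denominator; the case-count share is used because the
SOC profile is meant to describe where the *signals* mass, and it is
what the per-SOC detail tables drill into. PTs missing from the
user-supplied PT→SOC table aggregate under a reserved `UNMAPPED` class
and are counted separately, never silently dropped. The licensed MedDRA
dictionary cannot ship with the package, so the mapping is always a
user-supplied two-column TSV; the synthetic generator emits a matching
vocabulary file.

## Synthetic data generator

The generator emulates the structure of a FAERS window, not its content.
Each report draws one primary-suspect drug from configured marginals;
PT presence is per-PT Bernoulli with probability `baseline × ρ` for
planted (drug, PT) pairs and `baseline` otherwise; a report drawing no
PT receives one uniformly (every FAERS report has at least one REAC
row). Duplicates are re-emissions of an earlier CASEID into the same or
a later quarter with a strictly higher PRIMARYID and later-or-equal
FDA_DT — identical content, so deduplication is observable but cannot
change analysis results. Deleted cases are sampled independently.
Concomitant drug rows (role `C`) are added to a fraction of reports to
exercise the primary-suspect filter, and verbatim names mix generic and
brand spellings with occasional dose suffixes to exercise name matching.

Reference conditions (the defaults): 100 000 reports over 8 quarters;
three target drugs at marginal 0.10 each over nine background drugs
sharing 0.70; 200 PTs across 20 SOCs with baselines on a geometric grid
from 0.02 down to 0.002 (common clinical terms get the high end); ten
planted signals at ρ = 10 spread over the three target drugs, with
Diarrhoea deliberately planted for all three to reproduce the
class-wide-toxicity dilution seen in real TKI data; duplicate rate
0.15, deletion rate 0.02; 85% female among known sex; missingness 7%
(sex), 30% (age), 8% (occupation), 4% (country). A scenario helper
raises one drug's sex missingness to 96% to exercise the unknown-heavy
demographic paths that real neratinib reports show. These rates are
chosen as representative of oncology-drug FAERS windows; none is
calibrated to any particular measured outcome.

Closed-form expectations are exact under the model, including the
at-least-one-event correction: P(PT present | drug) =
`p + (1/K)·∏ⱼ(1 − pⱼ)` with `p = baseline × ρ`, and expected fourfold
counts scale by `(1 − deleted_rate)` because deletion is uniform.
Recovery tests compare empirical RORs to these expectations on the log
scale with the Wald standard error.

What the generator does **not** emulate: misspelled or free-text drug
names beyond dose suffixes, temporal reporting trends, correlated PT
co-occurrence beyond what shared drugs induce, outcome severity, and
reporter-dependent missingness. Passing tests therefore demonstrate the
correctness of the pipeline's bookkeeping and statistics under a known
model — they do not validate clinical conclusions drawn from real FAERS
extracts, which carry underreporting and confounding the model omits.

## Problem sizes and numerics

The test suite runs the full study at 10⁵ reports (a few seconds to
generate and read) and smaller 10⁴-report extracts for shared fixtures;
oracle equivalence uses 10⁴ random tables. Statistics are computed in
double precision from integer cells; ROR and PRR are formed as a single
quotient of integer products, so hand-checkable rational examples are
reproduced exactly. Determinism: a single `numpy` Generator seeded from
the configuration drives generation, so equal configs give
byte-identical files; pipeline outputs are deterministic functions of
their inputs, and stage-wise execution is byte-identical to the
end-to-end run.

## Known limitations

* Only the exact CASEID rule is implemented; probabilistic duplicate
  detection (same patient, different CASEID) is out of scope.
* OUTC and RPSR tables are accepted but feed no computation, matching
  the analyses this pipeline produces; THER and INDI are parsed and
  carried but not used as filters.
* No Bayesian disproportionality (IC/BCPNN, EBGM) and no
  multiple-comparison correction: flags are threshold rules, and with
  hundreds of PTs per drug a nominal error rate across null pairs is
  expected and measured, not corrected away.
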
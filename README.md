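# pvsignal

Disproportionality signal detection on FAERS-format spontaneous
adverse-event reports.

Post-marketing drug safety surveillance asks whether a particular adverse
event is reported *disproportionately often* for one drug compared with
the background of all other reports in a spontaneous-reporting database
such as the FDA Adverse Event Reporting System (FAERS). `pvsignal` is a
tested, reusable pipeline for that analysis: it reads FAERS quarterly
ASCII extracts (`$`-delimited DEMO/DRUG/REAC/THER/INDI tables plus a
DELETED case list), deduplicates cases, builds per-drug primary-suspect
cohorts, computes the classical disproportionality statistics per MedDRA
preferred term (PT), and aggregates signals by System Organ Class (SOC).
It is aimed at pharmacoepidemiologists and pharmacists who want a
scriptable, auditable alternative to spreadsheet-based FAERS workflows.

Because FAERS extracts are large and MedDRA is licensed, the package
ships a synthetic-data generator that emulates the structure of real
FAERS quarters — duplicate CASEIDs across quarters, deleted cases,
primary-suspect role codes, missing demographics, and drug–event pairs
with planted reporting-rate multipliers — together with a ground-truth
manifest, so the entire pipeline is exercisable and verifiable offline.

## The statistics

For one target drug and one preferred term, reports are cross-classified
into the fourfold table

|                  | target PT | other PTs |
|------------------|-----------|-----------|
| target drug      | a         | b         |
| all other drugs  | c         | d         |

where the counting unit is the unique (report, PT) pair. Two criteria
are evaluated:

* **Reporting odds ratio (ROR).**
  `ROR = (a/c)/(b/d) = ad/bc`, with the log-normal Wald interval
  `95% CI = exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d))`.
  Signal when `a ≥ 3` and the CI lower bound exceeds 1.
* **MHRA criterion.**
  `PRR = [a/(a+b)] / [c/(c+d)]` and the Pearson chi-square
  `χ² = (ad − bc)²·N / [(a+b)(c+d)(a+c)(b+d)]` (no continuity
  correction). Signal when `a ≥ 3`, `PRR ≥ 2` and `χ² ≥ 4`.

The combined criterion — the default — is the conjunction of the two,
used to suppress false positives. Tables with a zero cell are marked
non-computable rather than corrected.

Deduplication follows the FDA rule for quarterly extracts: among records
sharing a CASEID, keep the one with the most recent FDA_DT, breaking
ties by the higher PRIMARYID; cases listed in the DELETED table are then
excluded.

## Worked example

Generate a synthetic extract (20 000 cases over four quarters, three
HER2-targeted kinase inhibitors over a nine-drug background, ten planted
signals at a 10× reporting-rate multiplier) and screen one drug:

```python
from pvsignal import default_config, generate

cfg = default_config(seed=11, n_quarters=4, n_reports_per_quarter=5000)
manifest = generate(cfg, "demo")
print(f"cases={manifest.n_cases} versions={manifest.n_emissions} "
      f"deleted={manifest.n_deleted_listed}")
# cases=20000 versions=23019 deleted=399
```

```bash
pv-signal signals --quarters demo --drug Tucatinib --pattern TUKYSA \
    --ptsoc demo/pt_soc_map.tsv --method combined --top 5
```

```text
     drug                                          pt   a    b    c     d      ror  ...      prr        chi2  combined_flag
Tucatinib                                     Fatigue 379 4165  336 32648 8.841817  ... 8.187757 1145.640782           True
Tucatinib                                      Nausea 377 4167  336 32648 8.790937  ... 8.144550 1135.022187           True
Tucatinib Palmar-plantar erythrodysaesthesia syndrome 328 4216  333 32651 7.628260  ... 7.149812  889.740333           True
Tucatinib                                   Diarrhoea 366 4178 1106 31878 2.524926  ... 2.402099  234.246369           True
```

The four flagged terms are exactly the four signals planted for
Tucatinib. `a` is the number of deduplicated Tucatinib reports carrying
the term; Fatigue's ROR of 8.84 says the odds of a Tucatinib report
mentioning fatigue are ~9× the background odds. Diarrhoea's lower ROR
(2.52) reflects that the same term is also planted for the other two
study drugs, which inflates its background rate `c` — a dilution effect
real class-wide toxicities show too.

Full runs are driven by one YAML config (`pv-signal run -c config.yaml`)
and write, per drug: a demographics summary, the full signal table, a
top-N-by-ROR table, the SOC distribution, per-SOC PT tables, and a run
log with row counts at every stage (read → dedup → deleted → cohort).
The same stages are available as standalone subcommands
(`simulate`, `ingest`, `dedup`, `signals`, `report`).

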
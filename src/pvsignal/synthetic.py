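"""Synthetic FAERS-format data with known ground truth.

Generates quarterly DEMO/DRUG/REAC/THER/INDI files (plus a DELETED list
and a PT->SOC vocabulary TSV) in the exact dialect :mod:`pvsignal.faers_io`
reads, together with a manifest of realized counts, so every pipeline
stage can be verified without downloading FAERS.

Generative model, per report:

* one primary-suspect drug drawn from the configured marginals, with an
  independent concomitant drug on a fraction of reports (exercises the
  primary-suspect filter);
* a PT set drawn by per-PT Bernoulli with probability ``baseline * rho``
  when the (drug, PT) pair is planted, ``baseline`` otherwise; a report
  drawing zero PTs is assigned one PT uniformly, so every report has at
  least one REAC row;
* demographics (sex, age with mixed AGE_COD units, occupation, reporter
  country) with configurable missingness, including per-drug sex
  missingness to mimic drugs reported almost entirely without gender;
* with probability ``duplicate_rate`` the case is re-emitted in a later
  (or the same) quarter under a new, higher PRIMARYID and a later-or-equal
  FDA_DT — the structure the deduplication rule exists to resolve;
* with probability ``deleted_rate`` the CASEID enters the DELETED list.

All randomness flows from the single seed; the same config yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

PRIMARYID_BASE = 100_000_001
CASEID_BASE = 10_000_001

SOC_NAMES = (
    "Gastrointestinal disorders",
    "General disorders and administration site conditions",
    "Skin and subcutaneous tissue disorders",
    "Injury, poisoning and procedural complications",
    "Nervous system disorders",
    "Neoplasms benign, malignant and unspecified",
    "Investigations",
    "Blood and lymphatic system disorders",
    "Metabolism and nutrition disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Musculoskeletal and connective tissue disorders",
    "Infections and infestations",
    "Cardiac disorders",
    "Vascular disorders",
    "Renal and urinary disorders",
    "Hepatobiliary disorders",
    "Eye disorders",
    "Psychiatric disorders",
    "Immune system disorders",
    "Surgical and medical procedures",
)

#: (PT, SOC) seed terms; fillers are appended round-robin over SOCs
SEED_PTS = (
    ("Diarrhoea", "Gastrointestinal disorders"),
    ("Nausea", "Gastrointestinal disorders"),
    ("Vomiting", "Gastrointestinal disorders"),
    ("Stomatitis", "Gastrointestinal disorders"),
    ("Constipation", "Gastrointestinal disorders"),
    ("Fatigue", "General disorders and administration site conditions"),
    ("Disease progression", "General disorders and administration site conditions"),
    ("Mucosal inflammation", "General disorders and administration site conditions"),
    ("Drug ineffective", "General disorders and administration site conditions"),
    ("Palmar-plantar erythrodysaesthesia syndrome", "Skin and subcutaneous tissue disorders"),
    ("Rash", "Skin and subcutaneous tissue disorders"),
    ("Alopecia", "Skin and subcutaneous tissue disorders"),
    ("Paronychia", "Infections and infestations"),
    ("Headache", "Nervous system disorders"),
    ("Dizziness", "Nervous system disorders"),
    ("Decreased appetite", "Metabolism and nutrition disorders"),
    ("Dehydration", "Metabolism and nutrition disorders"),
    ("Anaemia", "Blood and lymphatic system disorders"),
    ("Hepatotoxicity", "Hepatobiliary disorders"),
    ("Epistaxis", "Respiratory, thoracic and mediastinal disorders"),
)

COUNTRIES = ("US", "FR", "IN", "CN", "JP", "DE", "GB", "IT", "ES")
COUNTRY_WEIGHTS = (0.60, 0.10, 0.08, 0.06, 0.04, 0.04, 0.04, 0.02, 0.02)

OCCUPATIONS = ("MD", "PH", "OT", "HP", "CN", "LW")
OCCUPATION_WEIGHTS = (0.35, 0.10, 0.06, 0.04, 0.35, 0.10)


@dataclass(frozen=True)
class DrugSpec:
    """One drug in the vocabulary: label, name patterns (generic first,
    optional brand), and its marginal probability of being the primary
    suspect of a report."""

    label: str
    patterns: tuple[str, ...]
    marginal: float

    @property
    def generic(self) -> str:
        return self.patterns[0]


@dataclass(frozen=True)
class PtSpec:
    pt: str
    soc: str
    baseline: float  # per-report Bernoulli probability under the null


@dataclass(frozen=True)
class PlantedSignal:
    drug_label: str
    pt: str
    rho: float  # reporting-rate multiplier, >= 1


@dataclass(frozen=True)
class Missingness:
    sex: float = 0.07
    age: float = 0.30
    occupation: float = 0.08
    country: float = 0.04


@dataclass
class SimConfig:
    seed: int
    n_quarters: int = 8
    n_reports_per_quarter: int = 12_500
    drugs: tuple[DrugSpec, ...] = ()
    pts: tuple[PtSpec, ...] = ()
    planted: tuple[PlantedSignal, ...] = ()
    duplicate_rate: float = 0.15
    deleted_rate: float = 0.02
    missing: Missingness = field(default_factory=Missingness)
    sex_missing_by_drug: dict[str, float] = field(default_factory=dict)
    female_fraction: float = 0.85
    concomitant_rate: float = 0.30
    brand_name_fraction: float = 0.30
    dose_suffix_fraction: float = 0.30
    start_year: int = 2015

    def __post_init__(self):
        for p in (self.duplicate_rate, self.deleted_rate, self.female_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for s in self.planted:
            if s.rho < 1.0:
                raise ValueError("planted rho must be >= 1")
        if self.drugs and abs(sum(d.marginal for d in self.drugs) - 1.0) > 1e-9:
            raise ValueError("drug marginals must sum to 1")

    @property
    def n_reports(self) -> int:
        return self.n_quarters * self.n_reports_per_quarter


def _filler_pts(n: int) -> list[PtSpec]:
    """Deterministic filler vocabulary on a geometric baseline grid."""
    out = []
    for i in range(n):
        soc = SOC_NAMES[i % len(SOC_NAMES)]
        out.append(PtSpec(pt=f"Synthetic reaction {i:03d}", soc=soc, baseline=0.0))
    return out


def default_vocabularies(n_pts: int = 200) -> tuple[tuple[DrugSpec, ...], tuple[PtSpec, ...]]:
    """Study-shaped vocabulary: three HER2 TKIs over a background of nine
    other drugs, and ``n_pts`` PTs across 20 SOCs with baseline reporting
    probabilities spread geometrically over [0.002, 0.02]."""
    drugs = [
        DrugSpec("Tucatinib", ("TUCATINIB", "TUKYSA"), 0.10),
        DrugSpec("Lapatinib", ("LAPATINIB", "TYKERB"), 0.10),
        DrugSpec("Neratinib", ("NERATINIB", "NERLYNX"), 0.10),
    ]
    n_bg = 9
    for i in range(n_bg):
        drugs.append(
            DrugSpec(f"Background-{i + 1:02d}", (f"BACKDRUG{i + 1:02d}",), 0.70 / n_bg)
        )
    specs = list(SEED_PTS) + [
        (p.pt, p.soc) for p in _filler_pts(max(0, n_pts - len(SEED_PTS)))
    ]
    specs = specs[:n_pts]
    k = len(specs)
    # geometric grid, descending: the common clinical terms listed first get
    # the highest per-report probabilities (0.02 down to 0.002)
    baselines = 0.002 * np.power(10.0, (k - 1 - np.arange(k)) / max(k - 1, 1))
    pts = tuple(
        PtSpec(pt=name, soc=soc, baseline=float(b))
        for (name, soc), b in zip(specs, baselines)
    )
    return tuple(drugs), pts


DEFAULT_PLANTED = (
    PlantedSignal("Tucatinib", "Diarrhoea", 10.0),
    PlantedSignal("Tucatinib", "Palmar-plantar erythrodysaesthesia syndrome", 10.0),
    PlantedSignal("Tucatinib", "Fatigue", 10.0),
    PlantedSignal("Tucatinib", "Nausea", 10.0),
    PlantedSignal("Lapatinib", "Diarrhoea", 10.0),
    PlantedSignal("Lapatinib", "Rash", 10.0),
    PlantedSignal("Lapatinib", "Stomatitis", 10.0),
    PlantedSignal("Neratinib", "Diarrhoea", 10.0),
    PlantedSignal("Neratinib", "Vomiting", 10.0),
    PlantedSignal("Neratinib", "Constipation", 10.0),
)


def default_config(
    seed: int,
    n_quarters: int = 8,
    n_reports_per_quarter: int = 12_500,
    n_pts: int = 200,
    rho: float = 10.0,
) -> SimConfig:
    """The reference simulation: 3 target drugs + 9 background drugs,
    ``n_pts`` PTs, 10 planted (drug, PT) signals at rate multiplier ``rho``."""
    drugs, pts = default_vocabularies(n_pts)
    planted = tuple(dataclasses.replace(p, rho=rho) for p in DEFAULT_PLANTED)
    return SimConfig(
        seed=seed,
        n_quarters=n_quarters,
        n_reports_per_quarter=n_reports_per_quarter,
        drugs=drugs,
        pts=pts,
        planted=planted,
    )


def tki_scenario(seed: int, n_quarters: int = 4, n_reports_per_quarter: int = 2000) -> SimConfig:
    """Small demographic-pathology scenario: Neratinib reported with 96%
    missing sex, mirroring a drug whose reports almost never carry gender."""
    cfg = default_config(seed, n_quarters=n_quarters, n_reports_per_quarter=n_reports_per_quarter)
    cfg.sex_missing_by_drug = {"Neratinib": 0.96}
    return cfg


def config_from_dict(data: Mapping, seed: int | None = None) -> SimConfig:
    """Build a SimConfig from a plain mapping (YAML-friendly); omitted
    vocabularies fall back to the defaults."""
    data = dict(data)
    if seed is not None:
        data["seed"] = seed
    drugs_raw = data.pop("drugs", None)
    pts_raw = data.pop("pts", None)
    planted_raw = data.pop("planted", None)
    d_drugs, d_pts = default_vocabularies(int(data.pop("n_pts", 200)))
    drugs = (
        tuple(DrugSpec(d["label"], tuple(d["patterns"]), float(d["marginal"])) for d in drugs_raw)
        if drugs_raw
        else d_drugs
    )
    pts = (
        tuple(PtSpec(p["pt"], p["soc"], float(p["baseline"])) for p in pts_raw)
        if pts_raw
        else d_pts
    )
    planted = (
        tuple(PlantedSignal(s["drug"], s["pt"], float(s["rho"])) for s in planted_raw)
        if planted_raw is not None
        else DEFAULT_PLANTED
    )
    missing = Missingness(**data.pop("missing", {}))
    return SimConfig(drugs=drugs, pts=pts, planted=planted, missing=missing, **data)


# ---------------------------------------------------------------------------
# expectations under the generative model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpectedTable:
    """Closed-form expected fourfold counts (real-valued)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def ror(self) -> float:
        return (self.a * self.d) / (self.b * self.c)

    @property
    def prr(self) -> float:
        return (self.a / (self.a + self.b)) / (self.c / (self.c + self.d))


def _rho_matrix(config: SimConfig) -> np.ndarray:
    """(n_drugs, n_pts) multiplier matrix; 1 except at planted pairs."""
    drug_index = {d.label: i for i, d in enumerate(config.drugs)}
    pt_index = {p.pt: j for j, p in enumerate(config.pts)}
    rho = np.ones((len(config.drugs), len(config.pts)))
    for s in config.planted:
        if s.drug_label not in drug_index:
            raise KeyError(f"planted drug {s.drug_label!r} not in vocabulary")
        if s.pt not in pt_index:
            raise KeyError(f"planted PT {s.pt!r} not in vocabulary")
        rho[drug_index[s.drug_label], pt_index[s.pt]] = s.rho
    return rho


def presence_probabilities(config: SimConfig) -> np.ndarray:
    """(n_drugs, n_pts) matrix of P(PT present in a report | drug),
    including the guaranteed-at-least-one-event correction."""
    baselines = np.array([p.baseline for p in config.pts])
    p = baselines[None, :] * _rho_matrix(config)
    if (p > 1.0).any():
        raise ValueError("baseline * rho exceeds 1 for some planted pair")
    p_none = np.prod(1.0 - p, axis=1, keepdims=True)
    return p + p_none / p.shape[1]


def expected_table(config: SimConfig, drug_label: str, pt: str) -> ExpectedTable:
    """Expected a/b/c/d for one (drug, PT) pair after dedup and deletion.

    Duplicate re-emissions collapse under deduplication and deletions are
    uniform, so the expectation is the no-duplicate model scaled by
    ``1 - deleted_rate``.
    """
    labels = [d.label for d in config.drugs]
    pt_names = [p.pt for p in config.pts]
    if drug_label not in labels:
        raise KeyError(f"unknown drug {drug_label!r}")
    if pt not in pt_names:
        raise KeyError(f"unknown PT {pt!r}")
    di, pj = labels.index(drug_label), pt_names.index(pt)
    q = presence_probabilities(config)
    m = np.array([d.marginal for d in config.drugs])
    n_eff = config.n_reports * (1.0 - config.deleted_rate)
    row_pairs = q.sum(axis=1)  # expected pairs per report, by drug
    a = n_eff * m[di] * q[di, pj]
    b = n_eff * m[di] * (row_pairs[di] - q[di, pj])
    others = np.delete(np.arange(len(labels)), di)
    c = n_eff * float((m[others] * q[others, pj]).sum())
    d = n_eff * float((m[others] * (row_pairs[others] - q[others, pj])).sum())
    return ExpectedTable(a=a, b=b, c=c, d=d)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthManifest:
    """Realized ground truth emitted next to the files.

    Sufficient to verify every stage: physical row counts per quarter,
    the unique-case and deletion counts the dedup stage must recover,
    per-drug primary-suspect cohort sizes among surviving cases, realized
    pair counts for each planted signal, and realized missingness rates.
    """

    seed: int
    quarter_ids: list[str]
    n_cases: int
    n_emissions: int
    n_deleted_listed: int
    n_reports_final: int
    per_quarter_rows: dict[str, dict[str, int]]
    cohort_sizes: dict[str, int]
    planted: list[dict]
    total_unique_pairs: int
    realized_missing: dict[str, float]
    files: dict[str, dict[str, str]]
    pt_soc_map: str

    def to_json(self, path: Path | str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path: Path | str) -> "GroundTruthManifest":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _quarter_ids(config: SimConfig) -> list[str]:
    out = []
    for i in range(config.n_quarters):
        year = config.start_year + i // 4
        out.append(f"{year}q{i % 4 + 1}")
    return out


def _quarter_bounds(config: SimConfig):
    """np.datetime64 start and day counts for each quarter."""
    starts, ndays = [], []
    for i in range(config.n_quarters):
        year = config.start_year + i // 4
        month = (i % 4) * 3 + 1
        start = np.datetime64(f"{year}-{month:02d}-01")
        if month == 10:
            end = np.datetime64(f"{year + 1}-01-01")
        else:
            end = np.datetime64(f"{year}-{month + 3:02d}-01")
        starts.append(start)
        ndays.append(int((end - start) / np.timedelta64(1, "D")))
    return np.array(starts), np.array(ndays)


def _dates_to_int(dates: np.ndarray) -> np.ndarray:
    di = pd.DatetimeIndex(dates)
    return (di.year * 10_000 + di.month * 100 + di.day).to_numpy()


def generate(config: SimConfig, out_dir: Path | str) -> GroundTruthManifest:
    """Write one synthetic FAERS extract and return its manifest.

    Also writes ``pt_soc_map.tsv`` (the synthetic MedDRA stand-in) and
    ``manifest.json`` into ``out_dir``.
    """
    if not config.drugs or not config.pts:
        raise ValueError("drug and PT vocabularies must be nonempty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    n_drugs, n_pts = len(config.drugs), len(config.pts)
    qids = _quarter_ids(config)

    marginals = np.array([d.marginal for d in config.drugs])
    drug_idx = rng.choice(n_drugs, size=n, p=marginals)
    quarter_idx = np.repeat(np.arange(config.n_quarters), config.n_reports_per_quarter)

    # --- adverse events: per-PT Bernoulli, planted pairs multiplied by rho
    baselines = np.array([p.baseline for p in config.pts])
    rho = _rho_matrix(config)
    ev_case_parts, ev_pt_parts = [], []
    for d in range(n_drugs):
        rows = np.flatnonzero(drug_idx == d)
        if rows.size == 0:
            continue
        p = baselines * rho[d]
        draws = rng.random((rows.size, n_pts)) < p
        none = ~draws.any(axis=1)
        if none.any():
            draws[np.flatnonzero(none), rng.integers(0, n_pts, int(none.sum()))] = True
        r_i, p_j = np.nonzero(draws)
        ev_case_parts.append(rows[r_i])
        ev_pt_parts.append(p_j)
    ev_case = np.concatenate(ev_case_parts)
    ev_pt = np.concatenate(ev_pt_parts)
    order = np.lexsort((ev_pt, ev_case))
    ev_case, ev_pt = ev_case[order], ev_pt[order]

    # --- demographics
    sex_missing = np.full(n_drugs, config.missing.sex)
    for label, rate in config.sex_missing_by_drug.items():
        sex_missing[[d.label for d in config.drugs].index(label)] = rate
    miss_sex = rng.random(n) < sex_missing[drug_idx]
    female = rng.random(n) < config.female_fraction
    sex = np.where(miss_sex, "U", np.where(female, "F", "M"))

    miss_age = rng.random(n) < config.missing.age
    age_years = np.clip(rng.normal(57.0, 13.0, n), 18.0, 90.0)
    age_cod = rng.choice(["YR", "DEC", "MON"], size=n, p=[0.90, 0.05, 0.05])
    age_val = np.where(
        age_cod == "YR",
        np.round(age_years, 1),
        np.where(age_cod == "DEC", np.round(age_years / 10.0, 2), np.round(age_years * 12.0)),
    )

    miss_occ = rng.random(n) < config.missing.occupation
    occp = rng.choice(OCCUPATIONS, size=n, p=OCCUPATION_WEIGHTS)
    miss_ctry = rng.random(n) < config.missing.country
    country = rng.choice(COUNTRIES, size=n, p=COUNTRY_WEIGHTS)

    # --- dates
    starts, ndays = _quarter_bounds(config)
    day_off = (rng.random(n) * ndays[quarter_idx]).astype(np.int64)
    fda = starts[quarter_idx] + day_off.astype("timedelta64[D]")
    fda_int = _dates_to_int(fda)

    # --- drug name rendering
    has_brand = np.array([len(d.patterns) > 1 for d in config.drugs])
    use_brand = (rng.random(n) < config.brand_name_fraction) & has_brand[drug_idx]
    add_dose = rng.random(n) < config.dose_suffix_fraction
    dose = rng.choice([50, 100, 150, 250], size=n)
    generic = np.array([d.generic for d in config.drugs])
    brandish = np.array([d.patterns[-1] for d in config.drugs])
    base_name = np.where(use_brand, brandish[drug_idx], generic[drug_idx])
    verbatim = np.where(
        add_dose,
        np.char.add(np.char.add(base_name.astype(str), " "), np.char.add(dose.astype(str), "MG")),
        base_name.astype(str),
    )
    prod_ai = generic[drug_idx]

    con_mask = rng.random(n) < config.concomitant_rate
    con_drug = rng.integers(0, n_drugs, n)

    # --- duplicates and deletions
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_rows = np.flatnonzero(dup_mask)
    dup_q = rng.integers(quarter_idx[dup_rows], config.n_quarters)
    same_q = dup_q == quarter_idx[dup_rows]
    dup_day = np.empty(dup_rows.size, dtype=np.int64)
    span_new = ndays[dup_q]
    dup_day[~same_q] = (rng.random((~same_q).sum()) * span_new[~same_q]).astype(np.int64)
    orig_day = day_off[dup_rows]
    room = np.maximum(ndays[dup_q] - orig_day, 1)
    dup_day[same_q] = orig_day[same_q] + (rng.random(same_q.sum()) * room[same_q]).astype(np.int64)
    dup_day = np.minimum(dup_day, ndays[dup_q] - 1)
    dup_fda_int = _dates_to_int(starts[dup_q] + dup_day.astype("timedelta64[D]"))

    del_mask = rng.random(n) < config.deleted_rate
    deleted_caseids = CASEID_BASE + np.flatnonzero(del_mask)

    # --- emissions (originals + duplicate re-submissions), PRIMARYID order
    em_case = np.concatenate([np.arange(n), dup_rows])
    em_quarter = np.concatenate([quarter_idx, dup_q])
    em_isdup = np.concatenate([np.zeros(n, np.int8), np.ones(dup_rows.size, np.int8)])
    em_fda = np.concatenate([fda_int, dup_fda_int])
    rank = np.lexsort((em_case, em_isdup, em_quarter))
    em_pid = np.empty(em_case.size, dtype=np.int64)
    em_pid[rank] = PRIMARYID_BASE + np.arange(em_case.size)

    # --- assemble output frames
    def fmt_age(v, cod, missing):
        vals = np.where(missing, "", np.char.mod("%g", v))
        cods = np.where(missing, "", cod)
        return vals, cods

    age_str, age_cod_str = fmt_age(age_val, age_cod, miss_age)
    occp_str = np.where(miss_occ, "", occp)
    ctry_str = np.where(miss_ctry, "", country)

    demo = pd.DataFrame(
        {
            "PRIMARYID": em_pid,
            "CASEID": CASEID_BASE + em_case,
            "FDA_DT": em_fda,
            "SEX": sex[em_case],
            "AGE": age_str[em_case],
            "AGE_COD": age_cod_str[em_case],
            "OCCP_COD": occp_str[em_case],
            "REPORTER_COUNTRY": ctry_str[em_case],
            "_q": em_quarter,
        }
    )

    ps_rows = pd.DataFrame(
        {
            "PRIMARYID": em_pid,
            "DRUG_SEQ": 1,
            "ROLE_COD": "PS",
            "DRUGNAME": verbatim[em_case],
            "PROD_AI": prod_ai[em_case],
            "_q": em_quarter,
        }
    )
    con_em = np.flatnonzero(con_mask[em_case])
    con_rows = pd.DataFrame(
        {
            "PRIMARYID": em_pid[con_em],
            "DRUG_SEQ": 2,
            "ROLE_COD": "C",
            "DRUGNAME": generic[con_drug[em_case[con_em]]],
            "PROD_AI": generic[con_drug[em_case[con_em]]],
            "_q": em_quarter[con_em],
        }
    )
    drug = pd.concat([ps_rows, con_rows], ignore_index=True).sort_values(
        ["_q", "PRIMARYID", "DRUG_SEQ"], kind="mergesort"
    )

    pt_names = np.array([p.pt for p in config.pts])
    ev_frame = pd.DataFrame({"case": ev_case, "PT": pt_names[ev_pt]})
    em_frame = pd.DataFrame({"case": em_case, "PRIMARYID": em_pid, "_q": em_quarter})
    reac = em_frame.merge(ev_frame, on="case", how="inner").sort_values(
        ["_q", "PRIMARYID", "PT"], kind="mergesort"
    )[["PRIMARYID", "PT", "_q"]]

    ther = pd.DataFrame(
        {"PRIMARYID": em_pid, "DSG_DRUG_SEQ": 1, "START_DT": em_fda, "_q": em_quarter}
    )
    tki_labels = {s.drug_label for s in config.planted}
    indi_pt = np.where(
        np.isin(np.array([config.drugs[i].label for i in range(n_drugs)])[drug_idx], list(tki_labels)),
        "Breast cancer",
        "Product used for unknown indication",
    )
    indi = pd.DataFrame(
        {"PRIMARYID": em_pid, "INDI_DRUG_SEQ": 1, "INDI_PT": indi_pt[em_case], "_q": em_quarter}
    )

    # --- write per-quarter files
    per_quarter_rows: dict[str, dict[str, int]] = {}
    files: dict[str, dict[str, str]] = {}
    for qi, qid in enumerate(qids):
        year, qn = qid.split("q")
        suffix = f"{int(year) % 100:02d}Q{qn}"
        files[qid] = {}
        per_quarter_rows[qid] = {}
        for name, frame in (
            ("demo", demo),
            ("drug", drug),
            ("reac", reac),
            ("ther", ther),
            ("indi", indi),
        ):
            sub = frame[frame["_q"] == qi].drop(columns="_q")
            path = out / f"{name.upper()}{suffix}.txt"
            sub.to_csv(path, sep="$", index=False, lineterminator="\n")
            files[qid][name] = path.name
            per_quarter_rows[qid][name] = len(sub)

    with open(out / "DELETED.txt", "w", encoding="utf-8") as fh:
        for cid in deleted_caseids:
            fh.write(f"{cid}\n")

    map_path = out / "pt_soc_map.tsv"
    with open(map_path, "w", encoding="utf-8") as fh:
        fh.write("pt\tsoc\n")
        for p in config.pts:
            fh.write(f"{p.pt}\t{p.soc}\n")

    # --- ground truth over surviving cases
    survive = ~del_mask
    labels = [d.label for d in config.drugs]
    cohort_sizes = {
        lab: int((survive & (drug_idx == i)).sum()) for i, lab in enumerate(labels)
    }
    surv_ev = survive[ev_case]
    total_pairs = int(surv_ev.sum())
    pt_index = {p.pt: j for j, p in enumerate(config.pts)}
    planted_records = []
    for s in config.planted:
        di = labels.index(s.drug_label)
        pj = pt_index[s.pt]
        realized_a = int(((drug_idx[ev_case] == di) & (ev_pt == pj) & surv_ev).sum())
        exp = expected_table(config, s.drug_label, s.pt)
        planted_records.append(
            {
                "drug": s.drug_label,
                "pt": s.pt,
                "rho": s.rho,
                "expected_a": exp.a,
                "expected_ror": exp.ror,
                "realized_a": realized_a,
            }
        )

    manifest = GroundTruthManifest(
        seed=config.seed,
        quarter_ids=qids,
        n_cases=n,
        n_emissions=int(em_case.size),
        n_deleted_listed=int(del_mask.sum()),
        n_reports_final=int(survive.sum()),
        per_quarter_rows=per_quarter_rows,
        cohort_sizes=cohort_sizes,
        planted=planted_records,
        total_unique_pairs=total_pairs,
        realized_missing={
            "sex": float(miss_sex.mean()),
            "age": float(miss_age.mean()),
            "occupation": float(miss_occ.mean()),
            "country": float(miss_ctry.mean()),
        },
        files=files,
        pt_soc_map=map_path.name,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
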
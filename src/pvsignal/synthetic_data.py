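"""Synthetic FAERS-dialect datasets with planted ground truth.

The generator emulates the statistical structure of a spontaneous-report
extract so every pipeline stage can be exercised and verified without the
real download: duplicate reports sharing a CASEID under different
FDA_DT/PRIMARYID, partial dates, missing sex/age/weight at realistic rates,
Zipf-distributed background event frequencies, drug-event associations
planted at configurable relative risk, outcome and country codes, and
Weibull-distributed onset times converted to therapy-start/event dates.

Every random draw flows from one seeded generator in a fixed, documented
order (drug assignment, dates, demographics, outcomes, countries, event
terms, onset times, precision degradation, verbatim names, duplicates), so
a config+seed pair always yields byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import faers_io
from .faers_io import RawQuarter

#: System organ classes used for the synthetic PT -> SOC map (real MedDRA
#: SOC names; the assignment of synthetic terms to them is arbitrary).
SOC_NAMES = [
    "Immune system disorders",
    "Skin and subcutaneous tissue disorders",
    "Nervous system disorders",
    "Renal and urinary disorders",
    "Injury, poisoning and procedural complications",
    "Hepatobiliary disorders",
    "General disorders and administration site conditions",
    "Gastrointestinal disorders",
    "Respiratory, thoracic and mediastinal disorders",
    "Congenital, familial and genetic disorders",
    "Blood and lymphatic system disorders",
    "Musculoskeletal and connective tissue disorders",
    "Investigations",
    "Surgical and medical procedures",
    "Vascular disorders",
    "Metabolism and nutrition disorders",
    "Cardiac disorders",
    "Pregnancy, puerperium and perinatal conditions",
    "Infections and infestations",
    "Psychiatric disorders",
]

#: Terms that exercise the exclusion filter (mapped to the injury/
#: procedural SOC); appended after the numbered background vocabulary.
EXCLUSION_EXERCISE_PTS = ["Off label use", "Product dose omission",
                          "Drug ineffective"]

BACKGROUND_DRUG_NAMES = [
    "ASPIRIN", "IBUPROFEN", "METFORMIN", "LISINOPRIL", "ATORVASTATIN",
    "OMEPRAZOLE", "LEVOTHYROXINE", "AMOXICILLIN", "PREDNISONE", "WARFARIN",
]


def pt_vocabulary(n_background_pts: int) -> list[str]:
    """Synthetic preferred-term names: numbered terms in Zipf rank order,
    then the exclusion-exercise terms."""
    names = [f"Event term {i:03d}" for i in range(1, n_background_pts + 1)]
    return names + EXCLUSION_EXERCISE_PTS


def default_pt_soc_map(n_background_pts: int) -> dict[str, str]:
    mapping = {f"Event term {i:03d}": SOC_NAMES[(i - 1) % len(SOC_NAMES)]
               for i in range(1, n_background_pts + 1)}
    for pt in EXCLUSION_EXERCISE_PTS:
        mapping[pt] = "Injury, poisoning and procedural complications"
    return mapping


@dataclass(frozen=True)
class Planted:
    """One planted drug-event association at a given relative risk."""

    drug: str
    pt: str
    relative_risk: float


@dataclass
class DrugProfile:
    """Per-drug generator settings: report share, name pool, demographics,
    outcome/country laws and the Weibull onset-time law (scale days, shape)."""

    name: str
    share: float
    synonyms: list[str]
    sex_probs: tuple[float, float, float] = (0.50, 0.42, 0.08)  # F, M, unknown
    outcome_probs: dict[str, float] = field(default_factory=lambda: {
        "OT": 0.30, "HO": 0.17, "DE": 0.08, "LT": 0.03, "DS": 0.03,
        "unknown": 0.39})
    country_probs: dict[str, float] = field(default_factory=lambda: {
        "US": 0.55, "GB": 0.08, "JP": 0.06, "DE": 0.06, "FR": 0.05,
        "IN": 0.05, "unknown": 0.15})
    tto_weibull: tuple[float, float] = (300.0, 1.0)
    indication: str = "Hypertension"


def _penicillamine_profile() -> DrugProfile:
    # Demographic and outcome laws mirror the published report-level
    # margins for this drug (sex 54.5/36.7/8.8; serious outcomes ~33.7%;
    # US share 48.6%); onset times follow its fitted Weibull law.
    return DrugProfile(
        name="penicillamine", share=0.05,
        synonyms=["Penicillamine", "D-penicillamine", "Penicilamine",
                  "CUPRIMINE", "Depen"],
        sex_probs=(0.545, 0.367, 0.088),
        outcome_probs={"OT": 0.352, "HO": 0.188, "DE": 0.095, "LT": 0.032,
                       "DS": 0.023, "unknown": 0.310},
        country_probs={"US": 0.486, "GB": 0.063, "IN": 0.070, "DE": 0.048,
                       "JP": 0.043, "TR": 0.041, "unknown": 0.063,
                       "other": 0.186},
        tto_weibull=(453.17, 0.55),
        indication="Wilson's disease",
    )


def _trientine_profile() -> DrugProfile:
    return DrugProfile(
        name="trientine", share=0.035,
        synonyms=["Trientine", "Trientine HCl", "Trientine hydrochloride",
                  "SYPRINE", "Cuprior"],
        sex_probs=(0.424, 0.380, 0.196),
        outcome_probs={"OT": 0.165, "HO": 0.148, "DE": 0.077, "LT": 0.007,
                       "DS": 0.034, "unknown": 0.569},
        country_probs={"US": 0.855, "GB": 0.017, "FR": 0.040,
                       "unknown": 0.024, "other": 0.064},
        tto_weibull=(177.20, 0.76),
        indication="Wilson's disease",
    )


@dataclass
class SimConfig:
    """Full generator configuration; ``seed`` is mandatory."""

    seed: int
    n_reports: int = 5000
    drugs: list[DrugProfile] = field(default_factory=lambda: [
        _penicillamine_profile(), _trientine_profile()])
    n_background_pts: int = 200
    zipf_exponent: float = 1.5
    planted: list[Planted] = field(default_factory=list)
    duplicate_rate: float = 0.05
    missing_age: float = 0.45
    missing_weight: float = 0.85
    mean_extra_pts: float = 2.3          # PTs per report = 1 + Poisson(this)
    age_bins: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(1, 19, 0.15), (20, 40, 0.40),
                                 (41, 65, 0.35), (66, 90, 0.10)])
    exclusion_pt_weight_rank: int = 20   # Zipf rank whose weight the
    # exclusion-exercise terms borrow
    month_precision_fraction: float = 0.10  # start/event dates degraded
    target_concomitant_rate: float = 0.01   # background reports carrying a
    # target drug as concomitant
    quarters: list[str] = field(default_factory=lambda: [
        "2023q1", "2023q2", "2023q3", "2023q4",
        "2024q1", "2024q2", "2024q3", "2024q4"])
    background_sex_probs: tuple[float, float, float] = (0.52, 0.40, 0.08)
    background_tto_weibull: tuple[float, float] = (300.0, 1.0)

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be non-negative")
        shares = sum(d.share for d in self.drugs)
        if not 0 <= shares <= 1:
            raise ValueError("drug shares must sum to within [0, 1]")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        for frac in (self.missing_age, self.missing_weight,
                     self.month_precision_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        for p in self.planted:
            if p.relative_risk <= 0:
                raise ValueError("relative_risk must be positive")
            if p.drug not in {d.name for d in self.drugs}:
                raise ValueError(f"planted drug {p.drug!r} not configured")
        if not self.quarters:
            raise ValueError("at least one quarter required")


def default_planted(config_pts: int = 200) -> list[Planted]:
    """The preset plantings: relative risks 15, 5 and 1 per study drug at
    mid-frequency background ranks."""
    return [
        Planted("penicillamine", "Event term 012", 15.0),
        Planted("penicillamine", "Event term 025", 5.0),
        Planted("penicillamine", "Event term 040", 1.0),
        Planted("trientine", "Event term 018", 15.0),
        Planted("trientine", "Event term 030", 5.0),
        Planted("trientine", "Event term 050", 1.0),
    ]


def paper_like_config(seed: int, n_reports: int = 20000,
                      planted: list[Planted] | None = None,
                      **overrides) -> SimConfig:
    """The standard study-condition preset: two copper chelators against a
    large background, plantings at relative risks {15, 5, 1}."""
    if planted is None:
        planted = default_planted()
    return SimConfig(seed=seed, n_reports=n_reports, planted=planted,
                     **overrides)


@dataclass
class SimTruth:
    """Ground truth serialized alongside a generated dataset."""

    planted: list[Planted]
    drug_of_caseid: dict[str, str]          # caseid -> drug name/background
    canonical_primaryid: dict[str, str]     # caseid -> surviving PRIMARYID
    tto_params: dict[str, tuple[float, float]]
    n_reports: int
    seed: int

    def planted_pts(self, drug: str, min_rr: float = 0.0) -> set[str]:
        return {p.pt for p in self.planted
                if p.drug == drug and p.relative_risk >= min_rr}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted": [asdict(p) for p in self.planted],
            "drug_of_caseid": self.drug_of_caseid,
            "canonical_primaryid": self.canonical_primaryid,
            "tto_params": {k: list(v) for k, v in self.tto_params.items()},
            "n_reports": self.n_reports,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted=[Planted(**p) for p in payload["planted"]],
            drug_of_caseid=payload["drug_of_caseid"],
            canonical_primaryid=payload["canonical_primaryid"],
            tto_params={k: tuple(v) for k, v in payload["tto_params"].items()},
            n_reports=payload["n_reports"],
            seed=payload["seed"],
        )


@dataclass
class SimReport:
    """Internal representation of one generated case (pre-duplication)."""

    caseid: str
    primaryid: str
    fda_date: _dt.date
    quarter: str
    drug: str                 # canonical target name or "background"
    verbatim: str
    sex: str                  # F / M / ""
    age: float | None
    weight: float | None
    country: str
    outcome: str              # code or "unknown"
    events: list[str]
    start_date: _dt.date
    event_date: _dt.date
    start_precision: str = "day"   # day | month
    event_precision: str = "day"
    concomitant_target: str | None = None
    rpsr: str = "HP"


_QUARTER_STARTS = {1: (1, 1), 2: (4, 1), 3: (7, 1), 4: (10, 1)}


def _quarter_range(label: str) -> tuple[_dt.date, _dt.date]:
    year, q = int(label[:4]), int(label[-1])
    start = _dt.date(year, *_QUARTER_STARTS[q])
    if q == 4:
        end = _dt.date(year + 1, 1, 1)
    else:
        end = _dt.date(year, *_QUARTER_STARTS[q + 1])
    return start, end


def _categorical(rng: np.random.Generator, probs: dict[str, float],
                 size: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.array(keys, dtype=object)[idx]


def _draw_events(rng: np.random.Generator, weights: np.ndarray,
                 ks: np.ndarray, vocab: list[str]) -> list[list[str]]:
    """Weighted sampling without replacement per report via Gumbel top-k."""
    n = ks.size
    if n == 0:
        return []
    logw = np.log(weights)
    keys = logw[None, :] + rng.gumbel(size=(n, weights.size))
    order = np.argsort(-keys, axis=1)
    vocab_arr = np.array(vocab, dtype=object)
    return [list(vocab_arr[order[i, :ks[i]]]) for i in range(n)]


def simulate_reports(config: SimConfig) -> tuple[list[SimReport], SimTruth]:
    """Draw all case reports (before duplicate injection)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    vocab = pt_vocabulary(config.n_background_pts)

    # 1. drug assignment
    group_names = ["background"] + [d.name for d in config.drugs]
    group_probs = {"background": 1.0 - sum(d.share for d in config.drugs)}
    group_probs.update({d.name: d.share for d in config.drugs})
    assigned = _categorical(rng, group_probs, n)

    # 2. quarter and FDA receipt date
    quarter_idx = rng.integers(0, len(config.quarters), size=n)
    fda_dates = np.empty(n, dtype=object)
    for qi, label in enumerate(config.quarters):
        mask = quarter_idx == qi
        start, end = _quarter_range(label)
        span = (end - start).days
        offsets = rng.integers(0, span, size=int(mask.sum()))
        fda_dates[mask] = np.array(
            [start + _dt.timedelta(days=int(o)) for o in offsets], dtype=object)

    profiles = {d.name: d for d in config.drugs}

    # 3. sex per report (per-drug law)
    sexes = np.empty(n, dtype=object)
    for g in group_names:
        mask = assigned == g
        probs = (config.background_sex_probs if g == "background"
                 else profiles[g].sex_probs)
        draws = _categorical(rng, {"F": probs[0], "M": probs[1],
                                   "": probs[2]}, int(mask.sum()))
        sexes[mask] = draws

    # 4. age: bin then uniform within; missing fraction blanked
    bin_probs = {i: w for i, (_, _, w) in enumerate(config.age_bins)}
    age_bin = _categorical(rng, bin_probs, n).astype(int)
    lows = np.array([config.age_bins[i][0] for i in age_bin])
    highs = np.array([config.age_bins[i][1] for i in age_bin])
    ages = np.round(lows + rng.random(n) * (highs - lows), 0)
    ages_missing = rng.random(n) < config.missing_age

    # 5. weight
    weights_kg = np.round(rng.normal(70, 15, size=n).clip(30, 160), 1)
    weight_missing = rng.random(n) < config.missing_weight

    # 6. country, 7. outcome, rpsr
    countries = np.empty(n, dtype=object)
    outcomes = np.empty(n, dtype=object)
    for g in group_names:
        mask = assigned == g
        profile = profiles.get(g)
        cp = (profile.country_probs if profile else
              DrugProfile(name="", share=0, synonyms=[]).country_probs)
        op = (profile.outcome_probs if profile else
              DrugProfile(name="", share=0, synonyms=[]).outcome_probs)
        countries[mask] = _categorical(rng, cp, int(mask.sum()))
        outcomes[mask] = _categorical(rng, op, int(mask.sum()))
    rpsr = _categorical(rng, {"HP": 0.55, "CSM": 0.30, "OT": 0.15}, n)

    # 8. number of PTs per report
    ks = 1 + rng.poisson(config.mean_extra_pts, size=n)
    ks = np.minimum(ks, len(vocab))

    # 9. event-term selection: Zipf background weights, exclusion terms at a
    # fixed mid rank, planted pairs multiply the target drug's weight only
    ranks = np.arange(1, config.n_background_pts + 1, dtype=float)
    base = ranks ** (-config.zipf_exponent)
    excl_w = float(config.exclusion_pt_weight_rank) ** (-config.zipf_exponent)
    base = np.concatenate([base, np.full(len(EXCLUSION_EXERCISE_PTS), excl_w)])
    pt_index = {pt: i for i, pt in enumerate(vocab)}
    events: list[list[str] | None] = [None] * n
    for g in group_names:
        mask = assigned == g
        w = base.copy()
        for p in config.planted:
            if p.drug == g:
                w[pt_index[p.pt]] *= p.relative_risk
        drawn = _draw_events(rng, w, ks[mask], vocab)
        for pos, ev in zip(np.flatnonzero(mask), drawn):
            events[pos] = ev

    # 10. onset times -> start/event dates (event = start + tto;
    # start = fda - lag - tto)
    ttos = np.empty(n, dtype=float)
    for g in group_names:
        mask = assigned == g
        scale, shape = (config.background_tto_weibull if g == "background"
                        else profiles[g].tto_weibull)
        ttos[mask] = scale * rng.weibull(shape, size=int(mask.sum()))
    tto_days = np.maximum(1, np.round(ttos)).astype(int)
    lags = rng.integers(0, 60, size=n)

    # 11. precision degradation
    degrade = rng.random(n) < config.month_precision_fraction

    # 12. verbatim names
    verbatims = np.empty(n, dtype=object)
    for g in group_names:
        mask = assigned == g
        pool = (BACKGROUND_DRUG_NAMES if g == "background"
                else profiles[g].synonyms)
        verbatims[mask] = np.array(pool, dtype=object)[
            rng.integers(0, len(pool), size=int(mask.sum()))]

    # 13. concomitant target mentions on background reports
    conc = rng.random(n) < config.target_concomitant_rate
    conc_pick = rng.integers(0, max(len(config.drugs), 1), size=n)

    reports: list[SimReport] = []
    truth_drug: dict[str, str] = {}
    for i in range(n):
        caseid = str(1000001 + i)
        fda = fda_dates[i]
        event_date = fda - _dt.timedelta(days=int(lags[i]))
        start_date = event_date - _dt.timedelta(days=int(tto_days[i]))
        concomitant = None
        if assigned[i] == "background" and conc.size and conc[i] and config.drugs:
            concomitant = config.drugs[conc_pick[i]].synonyms[0]
        reports.append(SimReport(
            caseid=caseid,
            primaryid=caseid + "1",
            fda_date=fda,
            quarter=config.quarters[quarter_idx[i]],
            drug=str(assigned[i]),
            verbatim=str(verbatims[i]),
            sex=str(sexes[i]),
            age=None if ages_missing[i] else float(ages[i]),
            weight=None if weight_missing[i] else float(weights_kg[i]),
            country=str(countries[i]) if countries[i] != "unknown" else "",
            outcome=str(outcomes[i]),
            events=events[i] or [],
            start_date=start_date,
            event_date=event_date,
            start_precision="month" if degrade[i] else "day",
            event_precision="month" if degrade[i] else "day",
            concomitant_target=concomitant,
            rpsr=str(rpsr[i]),
        ))
        truth_drug[caseid] = str(assigned[i])

    truth = SimTruth(
        planted=list(config.planted),
        drug_of_caseid=truth_drug,
        canonical_primaryid={r.caseid: r.primaryid for r in reports},
        tto_params={**{d.name: d.tto_weibull for d in config.drugs},
                    "background": config.background_tto_weibull},
        n_reports=n,
        seed=config.seed,
    )
    return reports, truth


def inject_duplicates(reports: list[SimReport], rate: float,
                      seed: int) -> tuple[list[SimReport], dict[str, str]]:
    """Re-emit a fraction of cases as updated versions.

    Each selected CASEID gains one extra report with a strictly later
    FDA_DT, a higher PRIMARYID and possibly one event dropped; the later
    version is the canonical one (the record deduplication must keep).
    Returns the extended report list and caseid -> canonical PRIMARYID.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    selected = rng.random(len(reports)) < rate
    canonical = {r.caseid: r.primaryid for r in reports}
    extra: list[SimReport] = []
    for i, report in enumerate(reports):
        if not selected[i]:
            continue
        delay = int(rng.integers(30, 400))
        events = list(report.events)
        if len(events) > 1 and rng.random() < 0.3:
            events.pop(int(rng.integers(0, len(events))))
        dup = SimReport(**{**report.__dict__,
                           "primaryid": report.caseid + "2",
                           "fda_date": report.fda_date + _dt.timedelta(days=delay),
                           "events": events})
        extra.append(dup)
        canonical[report.caseid] = dup.primaryid
    return reports + extra, canonical


TABLE_HEADERS = {
    "demo": ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "SEX", "AGE",
             "AGE_COD", "WT", "WT_COD", "OCCR_COUNTRY"],
    "drug": ["PRIMARYID", "CASEID", "DRUG_SEQ", "ROLE_COD", "DRUGNAME"],
    "reac": ["PRIMARYID", "CASEID", "PT"],
    "ther": ["PRIMARYID", "CASEID", "DSG_DRUG_SEQ", "START_DT"],
    "indi": ["PRIMARYID", "CASEID", "INDI_DRUG_SEQ", "INDI_PT"],
    "outc": ["PRIMARYID", "CASEID", "OUTC_COD"],
    "rpsr": ["PRIMARYID", "CASEID", "RPSR_COD"],
}


def _date_token(date: _dt.date, precision: str) -> str:
    if precision == "month":
        return f"{date.year:04d}{date.month:02d}"
    return f"{date.year:04d}{date.month:02d}{date.day:02d}"


def _report_rows(report: SimReport, config: SimConfig):
    """Rows contributed by one report to each of the seven tables."""
    pid, cid = report.primaryid, report.caseid
    # FDA_DT may exceed the generating quarter for duplicates; that is
    # exactly how real updates arrive in later quarterly files.
    demo = {
        "PRIMARYID": pid, "CASEID": cid,
        "FDA_DT": _date_token(report.fda_date, "day"),
        "EVENT_DT": _date_token(report.event_date, report.event_precision),
        "SEX": report.sex,
        "AGE": "" if report.age is None else f"{report.age:.0f}",
        "AGE_COD": "" if report.age is None else "YR",
        "WT": "" if report.weight is None else f"{report.weight:g}",
        "WT_COD": "" if report.weight is None else "KG",
        "OCCR_COUNTRY": report.country,
    }
    drug_rows = [{"PRIMARYID": pid, "CASEID": cid, "DRUG_SEQ": "1",
                  "ROLE_COD": "PS", "DRUGNAME": report.verbatim}]
    ther_rows = [{"PRIMARYID": pid, "CASEID": cid, "DSG_DRUG_SEQ": "1",
                  "START_DT": _date_token(report.start_date,
                                          report.start_precision)}]
    if report.concomitant_target is not None:
        drug_rows.append({"PRIMARYID": pid, "CASEID": cid, "DRUG_SEQ": "2",
                          "ROLE_COD": "C",
                          "DRUGNAME": report.concomitant_target})
    reac_rows = [{"PRIMARYID": pid, "CASEID": cid, "PT": pt}
                 for pt in report.events]
    profile = {d.name: d for d in config.drugs}.get(report.drug)
    indi_rows = [{"PRIMARYID": pid, "CASEID": cid, "INDI_DRUG_SEQ": "1",
                  "INDI_PT": profile.indication if profile else "Hypertension"}]
    outc_rows = ([] if report.outcome == "unknown" else
                 [{"PRIMARYID": pid, "CASEID": cid, "OUTC_COD": report.outcome}])
    rpsr_rows = [{"PRIMARYID": pid, "CASEID": cid, "RPSR_COD": report.rpsr}]
    return {"demo": [demo], "drug": drug_rows, "reac": reac_rows,
            "ther": ther_rows, "indi": indi_rows, "outc": outc_rows,
            "rpsr": rpsr_rows}


def reports_to_quarters(reports: Sequence[SimReport],
                        config: SimConfig) -> list[RawQuarter]:
    """Bucket report rows into per-quarter tables (a duplicate re-emission
    lands in the quarter of its original case)."""
    quarters = {label: RawQuarter(quarter_label=label)
                for label in config.quarters}
    for report in reports:
        rows = _report_rows(report, config)
        quarter = quarters[report.quarter]
        for table, table_rows in rows.items():
            quarter.rows(table).extend(table_rows)
    return [quarters[label] for label in config.quarters]


def simulate_dataset(config: SimConfig, out_dir: str | Path,
                     ) -> tuple[Path, SimTruth]:
    """Generate a full FAERS-dialect dataset on disk.

    Writes the seven tables per quarter, ``pt_soc.csv``, ``truth.json`` and
    ``config.json``; returns the dataset directory and the ground truth.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    reports, truth = simulate_reports(config)
    reports, canonical = inject_duplicates(reports, config.duplicate_rate,
                                           seed=config.seed + 1)
    truth.canonical_primaryid = canonical

    for quarter in reports_to_quarters(reports, config):
        faers_io.write_quarter(quarter, out_dir, TABLE_HEADERS)

    from .contingency import PtSocMap
    PtSocMap(default_pt_soc_map(config.n_background_pts)).to_csv(
        out_dir / "pt_soc.csv")
    truth.to_json(out_dir / "truth.json")
    (out_dir / "config.json").write_text(json.dumps(
        _config_payload(config), indent=1, sort_keys=True))
    return out_dir, truth


def _config_payload(config: SimConfig) -> dict:
    payload = asdict(config)
    return payload


def load_quarters(data_dir: str | Path, delimiter: str = "$",
                  ) -> list[RawQuarter]:
    """Parse every quarter found in a dataset directory (files named
    ``DEMO<label>.txt`` etc.)."""
    data_dir = Path(data_dir)
    labels = sorted({p.stem[4:] for p in data_dir.glob("DEMO*.txt")})
    quarters = []
    for label in labels:
        paths = {}
        for table in faers_io.TABLE_NAMES:
            path = data_dir / f"{table.upper()}{label}.txt"
            if path.exists():
                paths[table] = path
        quarters.append(faers_io.parse_quarter(paths, quarter_label=label,
                                               delimiter=delimiter))
    return quarters


def truth_eval(signals, truth: SimTruth, drug: str,
               ) -> tuple[float, float]:
    """(sensitivity, false-positive fraction) of a screen against the truth.

    Sensitivity = planted PTs of the drug flagged / planted; the
    false-positive fraction divides flagged non-planted PTs by the
    non-planted PTs the screen actually tested for the drug.
    """
    if drug not in truth.tto_params:
        raise ValueError(f"truth/dataset mismatch: no drug {drug!r} in truth")
    planted = truth.planted_pts(drug)
    tested = {s.pt for s in signals}
    flagged = {s.pt for s in signals if s.combined_signal and not s.excluded}
    sens = (len(flagged & planted) / len(planted)) if planted else 0.0
    non_planted = tested - planted
    fpf = (len(flagged - planted) / len(non_planted)) if non_planted else 0.0
    return sens, fpf
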
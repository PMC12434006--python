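"""Synthetic spontaneous-reporting-system generator in the FAERS dialect.

Emits quarterly ASCII packages with fully known statistical structure so
every pipeline stage — parsing, deduplication, deletion, cohort
assignment, disproportionality screening, SOC aggregation — can be
tested without any download. Each synthetic case carries demographics,
one or more drug records consistent with its study group, one or more
reaction PTs drawn from a group-specific multinomial, outcome codes,
and therapy/event dates following a log-normal onset model. Reporting-
rate multipliers λ planted on chosen (group, PT) pairs create true
disproportionality signals; λ = 1 everywhere yields exact independence
by construction. Duplicate superseded report versions and a deletion
list exercise the cleaning stage, and the emitted ground truth records
exactly what the pipeline should recover.

Default parameters mirror the reporting profile of the checkpoint-
inhibitor study population this package models: six study groups with
sizes proportional to the reported 7,386 / 29,544 / 5,278 / 25 /
12,256 / 563 cases inside a background that is 25% other drugs,
≈2.14 AE records per case, 76% missing onset, and onset medians of
50 days (single agents) vs 36 days (dual therapy).
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import faers_io
from .records import (
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PartialDate,
    QuarterlyPackage,
    ReacRecord,
    TherRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PtSpec",
    "SignalSpec",
    "GroupProfile",
    "SyntheticConfig",
    "GroundTruth",
    "default_pt_vocab",
    "default_config",
    "generate",
    "expected_table",
]

ALL_GROUPS = ("IPI", "NIVO", "DURVA", "TREME", "IPI_NIVO", "DURVA_TREME", "OTHER")
COMBO_PARTNERS = {
    "IPI_NIVO": ("ipilimumab", "nivolumab"),
    "DURVA_TREME": ("durvalumab", "tremelimumab"),
}
MONO_DRUG = {
    "IPI": "ipilimumab",
    "NIVO": "nivolumab",
    "DURVA": "durvalumab",
    "TREME": "tremelimumab",
}

# raw-name variants exercising case, brand and strength-suffix noise
NAME_VARIANTS = {
    "ipilimumab": ["IPILIMUMAB", "Yervoy", "YERVOY.", "IPILIMUMAB 50 MG"],
    "nivolumab": ["NIVOLUMAB", "Opdivo", "OPDIVO.", "Nivolumab 240 MG"],
    "durvalumab": ["DURVALUMAB", "Imfinzi", "IMFINZI.", "DURVALUMAB 500 MG"],
    "tremelimumab": ["TREMELIMUMAB", "Imjudo", "IMJUDO.", "TREMELIMUMAB 25 MG"],
}
NON_STUDY_DRUGS = [
    "PEMBROLIZUMAB",
    "ATEZOLIZUMAB",
    "PACLITAXEL",
    "CARBOPLATIN",
    "DEXAMETHASONE",
    "METFORMIN",
    "OMEPRAZOLE",
    "ASPIRIN",
]

SEX_CODES = ("F", "M", None)
AGE_BANDS = ((0, 17), (18, 44), (45, 64), (65, 74), (75, 95), None)  # None = unspecified
COUNTRIES = ("US", "JP", "FR", "CN", "DE", "GB", "IT", "CA", "AU", "BR")
OCCUPATIONS = ("MD", "PH", "OT", "CN", "LW", None)
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
YEARS = tuple(range(2011, 2025))


@dataclass(frozen=True)
class PtSpec:
    name: str
    soc: str
    baseline_prob: float


@dataclass(frozen=True)
class SignalSpec:
    group: str
    pt: str
    multiplier: float  # λ ≥ 0 applied to the PT's baseline reporting rate


@dataclass
class GroupProfile:
    """Per-group demographic and clinical reporting parameters."""

    sex_probs: tuple = (0.28, 0.52, 0.20)  # F, M, unspecified
    age_band_probs: tuple = (0.002, 0.045, 0.22, 0.19, 0.12, 0.423)
    country_probs: tuple = (0.47, 0.16, 0.07, 0.05, 0.05, 0.05, 0.04, 0.04, 0.04, 0.03)
    occupation_probs: tuple = (0.32, 0.18, 0.16, 0.32, 0.001, 0.019)
    serious_prob: float = 0.85
    outcome_probs: dict = field(
        default_factory=lambda: {
            "DE": 0.30, "LT": 0.04, "HO": 0.28, "DS": 0.012,
            "CA": 0.0005, "RI": 0.001, "OT": 0.75,
        }
    )
    onset_median_days: float = 50.0
    onset_sigma: float = 1.2
    year_probs: tuple = (
        0.006, 0.019, 0.015, 0.022, 0.041, 0.105, 0.131, 0.112,
        0.121, 0.102, 0.096, 0.085, 0.063, 0.082,
    )

    def validate(self) -> None:
        for name in ("sex_probs", "age_band_probs", "country_probs", "occupation_probs", "year_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if (v < 0).any() or (v > 1).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be probabilities summing to 1")
        if not 0 <= self.serious_prob <= 1:
            raise ValueError("serious_prob outside [0, 1]")
        for code, p in self.outcome_probs.items():
            if code not in OUTCOME_CODES or not 0 <= p <= 1:
                raise ValueError(f"bad outcome prob {code}={p}")
        if self.onset_median_days <= 0 or self.onset_sigma <= 0:
            raise ValueError("onset model parameters must be positive")


def _dig_profile() -> GroupProfile:
    return GroupProfile(
        sex_probs=(0.29, 0.53, 0.18),
        age_band_probs=(0.002, 0.065, 0.26, 0.215, 0.135, 0.323),
        occupation_probs=(0.155, 0.258, 0.14, 0.445, 0.0005, 0.0015),
        serious_prob=0.91,
        outcome_probs={
            "DE": 0.25, "LT": 0.065, "HO": 0.40, "DS": 0.011,
            "CA": 0.0005, "RI": 0.001, "OT": 0.82,
        },
        onset_median_days=36.0,
        onset_sigma=1.1,
        year_probs=(
            0.0, 0.0, 0.0003, 0.0009, 0.009, 0.030, 0.058, 0.083,
            0.130, 0.131, 0.137, 0.160, 0.147, 0.1138,
        ),
    )


def default_pt_vocab() -> list[PtSpec]:
    """A 40-term vocabulary across 12 organ classes, rates decaying Zipf-like.

    Terms and classes follow the immune-related adverse-event spectrum
    of checkpoint-inhibitor reporting (colitis, endocrinopathies,
    hepatitis, myocarditis, cytokine release syndrome, ...) plus the
    high-volume generic terms every spontaneous-reporting database
    carries (death, disease progression, off-label use).
    """
    entries = [
        ("death", "General disorders"),
        ("malignant neoplasm progression", "Neoplasms"),
        ("diarrhoea", "Gastrointestinal disorders"),
        ("fatigue", "General disorders"),
        ("colitis", "Gastrointestinal disorders"),
        ("pyrexia", "General disorders"),
        ("off label use", "Injury and procedural complications"),
        ("rash", "Skin disorders"),
        ("nausea", "Gastrointestinal disorders"),
        ("pneumonitis", "Respiratory disorders"),
        ("hypothyroidism", "Endocrine disorders"),
        ("hepatitis", "Hepatobiliary disorders"),
        ("pruritus", "Skin disorders"),
        ("vomiting", "Gastrointestinal disorders"),
        ("asthenia", "General disorders"),
        ("adrenal insufficiency", "Endocrine disorders"),
        ("cytokine release syndrome", "Immune system disorders"),
        ("hyperthyroidism", "Endocrine disorders"),
        ("immune-mediated hepatitis", "Hepatobiliary disorders"),
        ("myocarditis", "Cardiac disorders"),
        ("acute kidney injury", "Renal and urinary disorders"),
        ("hypophysitis", "Endocrine disorders"),
        ("thyroiditis", "Endocrine disorders"),
        ("immune-mediated enterocolitis", "Gastrointestinal disorders"),
        ("hepatic function abnormal", "Hepatobiliary disorders"),
        ("myositis", "Musculoskeletal disorders"),
        ("arthralgia", "Musculoskeletal disorders"),
        ("type 1 diabetes mellitus", "Endocrine disorders"),
        ("diabetic ketoacidosis", "Metabolism disorders"),
        ("sepsis", "Infections"),
        ("pneumonia", "Infections"),
        ("anaemia", "Blood disorders"),
        ("decreased appetite", "Metabolism disorders"),
        ("headache", "Nervous system disorders"),
        ("dizziness", "Nervous system disorders"),
        ("interstitial lung disease", "Respiratory disorders"),
        ("blood creatinine increased", "Investigations"),
        ("alanine aminotransferase increased", "Investigations"),
        ("uveitis", "Eye disorders"),
        ("vitiligo", "Skin disorders"),
    ]
    # Zipf-ish decay normalised to 1
    weights = np.array([1.0 / (i + 2) ** 0.85 for i in range(len(entries))])
    weights /= weights.sum()
    return [PtSpec(name, soc, float(w)) for (name, soc), w in zip(entries, weights)]


@dataclass
class SyntheticConfig:
    """Full parameterisation of the synthetic reporting system."""

    seed: int = 0
    n_cases: int = 20_000
    group_weights: dict = field(
        default_factory=lambda: {
            "IPI": 0.100625, "NIVO": 0.402500, "DURVA": 0.071902,
            "TREME": 0.000341, "IPI_NIVO": 0.166964, "DURVA_TREME": 0.007668,
            "OTHER": 0.250000,
        }
    )
    pt_vocab: list = field(default_factory=default_pt_vocab)
    ae_extra_mean: float = 1.14  # AEs per case = 1 + Poisson(ae_extra_mean)
    signal_spec: list = field(
        default_factory=lambda: [
            SignalSpec("IPI_NIVO", "cytokine release syndrome", 5.0),
            SignalSpec("IPI_NIVO", "immune-mediated hepatitis", 4.0),
            SignalSpec("IPI_NIVO", "myocarditis", 2.5),
            SignalSpec("IPI", "colitis", 4.0),
            SignalSpec("NIVO", "pneumonitis", 4.0),
            SignalSpec("DURVA_TREME", "hepatitis", 4.0),
        ]
    )
    profiles: dict = field(
        default_factory=lambda: {
            **{g: GroupProfile() for g in ("IPI", "NIVO", "DURVA", "TREME", "OTHER")},
            **{g: _dig_profile() for g in ("IPI_NIVO", "DURVA_TREME")},
        }
    )
    missing_onset_rate: float = 0.76
    partial_date_rate: float = 0.05
    duplicate_rate: float = 0.17
    deleted_rate: float = 0.01
    combo_partner_ps_prob: float = 0.30  # else partner carries role SS
    concomitant_mean: float = 0.5

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be non-negative")
        w = np.array([self.group_weights.get(g, 0.0) for g in ALL_GROUPS], dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("group_weights must be non-negative and sum to 1")
        if set(self.group_weights) - set(ALL_GROUPS):
            raise ValueError("unknown group in group_weights")
        names = [p.name for p in self.pt_vocab]
        if len(set(names)) != len(names):
            raise ValueError("duplicate PT names in vocabulary")
        base = np.array([p.baseline_prob for p in self.pt_vocab], dtype=float)
        if (base <= 0).any() or abs(base.sum() - 1.0) > 1e-6:
            raise ValueError("baseline PT probabilities must be positive and sum to 1")
        for s in self.signal_spec:
            if s.group not in ALL_GROUPS or s.group == "OTHER":
                raise ValueError(f"signal on unknown group {s.group!r}")
            if s.pt not in names:
                raise ValueError(f"signal on unknown PT {s.pt!r}")
            if s.multiplier < 0:
                raise ValueError("multiplier must be ≥ 0")
        for rate in (
            self.missing_onset_rate, self.partial_date_rate,
            self.duplicate_rate, self.deleted_rate, self.combo_partner_ps_prob,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.ae_extra_mean < 0 or self.concomitant_mean < 0:
            raise ValueError("count means must be non-negative")
        for g in ALL_GROUPS:
            if g not in self.profiles:
                raise ValueError(f"missing profile for group {g}")
            self.profiles[g].validate()

    def pt_probs(self, group: str) -> np.ndarray:
        """Renormalised per-group PT multinomial (baseline × λ)."""
        base = np.array([p.baseline_prob for p in self.pt_vocab], dtype=float)
        mult = np.ones_like(base)
        index = {p.name: i for i, p in enumerate(self.pt_vocab)}
        for s in self.signal_spec:
            if s.group == group:
                mult[index[s.pt]] = s.multiplier
        probs = base * mult
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"group {group} has no reportable PT mass")
        return probs / total


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    cases: pd.DataFrame  # caseid, group, onset_days (NaN = missing)
    signals: pd.DataFrame  # group, pt, multiplier (planted pairs only)
    duplicate_primaryids: set
    deleted_caseids: set
    pt_soc: pd.DataFrame  # pt_name, soc_name for the vocabulary

    @property
    def surviving_caseids(self) -> set:
        return set(self.cases["caseid"]) - self.deleted_caseids

    def write(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        self.cases.to_csv(os.path.join(directory, "truth_cases.csv"), index=False)
        self.signals.to_csv(os.path.join(directory, "truth_signals.csv"), index=False)
        pd.DataFrame({"primaryid": sorted(self.duplicate_primaryids)}).to_csv(
            os.path.join(directory, "truth_duplicates.csv"), index=False
        )
        pd.DataFrame({"caseid": sorted(self.deleted_caseids)}).to_csv(
            os.path.join(directory, "truth_deleted.csv"), index=False
        )
        soc = self.pt_soc.copy()
        soc["soc_code"] = ["SOC%03d" % i for i in pd.factorize(soc["soc_name"])[0]]
        soc["is_primary_soc"] = "1"
        soc.to_csv(os.path.join(directory, "pt_soc_map.tsv"), sep="\t", index=False)


def default_config(seed: int = 0, n_cases: int = 20_000, **overrides) -> SyntheticConfig:
    cfg = SyntheticConfig(seed=seed, n_cases=n_cases)
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise AttributeError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def _draw_date(rng: np.random.Generator, year_probs: Sequence[float]) -> _dt.date:
    year = int(rng.choice(YEARS, p=np.asarray(year_probs) / np.sum(year_probs)))
    return _dt.date(year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))


def _full(date: _dt.date) -> PartialDate:
    return PartialDate(date.year, date.month, date.day)


def generate(
    config: SyntheticConfig, directory: str, write_truth: bool = True
) -> tuple[QuarterlyPackage, GroundTruth]:
    """Emit one quarterly package plus ground truth; deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    groups = [ALL_GROUPS[i] for i in rng.choice(
        len(ALL_GROUPS), size=n, p=[config.group_weights.get(g, 0.0) for g in ALL_GROUPS]
    )]
    pt_names = [p.name for p in config.pt_vocab]
    pt_prob_cache = {g: config.pt_probs(g) for g in ALL_GROUPS}

    demo: list[DemoRecord] = []
    drug: list[DrugRecord] = []
    reac: list[ReacRecord] = []
    outc: list[OutcRecord] = []
    ther: list[TherRecord] = []
    truth_rows = []
    duplicate_pids: set[str] = set()

    for i in range(n):
        g = groups[i]
        prof = config.profiles[g]
        caseid = str(10_000_000 + i)
        pid = caseid + "2"  # current version

        # demographics
        sex = SEX_CODES[int(rng.choice(3, p=prof.sex_probs))]
        band = AGE_BANDS[int(rng.choice(len(AGE_BANDS), p=prof.age_band_probs))]
        if band is None:
            age, age_cod = None, None
        else:
            age = float(rng.integers(band[0], band[1] + 1))
            age_cod = "YR"
            if age < 2:  # infants reported in months
                age, age_cod = age * 12, "MON"
        country = COUNTRIES[int(rng.choice(len(COUNTRIES), p=prof.country_probs))]
        occp = OCCUPATIONS[int(rng.choice(len(OCCUPATIONS), p=prof.occupation_probs))]

        # timeline: therapy start -> event -> FDA receipt
        fda_date = _draw_date(rng, prof.year_probs)
        onset = int(round(float(rng.lognormal(math.log(prof.onset_median_days), prof.onset_sigma))))
        onset_missing = rng.random() < config.missing_onset_rate
        event_date = fda_date - _dt.timedelta(days=int(rng.integers(5, 61)))
        start_date = event_date - _dt.timedelta(days=onset)
        event_dt: Optional[PartialDate] = None if onset_missing else _full(event_date)
        if event_dt is not None and rng.random() < config.partial_date_rate:
            event_dt = PartialDate(event_date.year, event_date.month)  # demoted

        demo.append(
            DemoRecord(
                primaryid=pid, caseid=caseid, fda_dt=_full(fda_date), event_dt=event_dt,
                age=age, age_cod=age_cod, sex=sex, occp_cod=occp,
                reporter_country=country, occr_country=country,
            )
        )

        # drug records
        seq = 1
        case_drugs: list[DrugRecord] = []

        def _variant(canonical: str) -> str:
            opts = NAME_VARIANTS[canonical]
            return opts[int(rng.integers(len(opts)))]

        if g in MONO_DRUG:
            canonical = MONO_DRUG[g]
            case_drugs.append(DrugRecord(pid, str(seq), "PS", _variant(canonical), canonical.upper()))
            seq += 1
        elif g in COMBO_PARTNERS:
            first, second = COMBO_PARTNERS[g]
            if rng.random() < 0.5:
                first, second = second, first
            case_drugs.append(DrugRecord(pid, str(seq), "PS", _variant(first), first.upper()))
            seq += 1
            partner_role = "PS" if rng.random() < config.combo_partner_ps_prob else "SS"
            case_drugs.append(DrugRecord(pid, str(seq), partner_role, _variant(second), second.upper()))
            seq += 1
        else:  # OTHER: non-study primary suspect
            name = NON_STUDY_DRUGS[int(rng.integers(len(NON_STUDY_DRUGS)))]
            case_drugs.append(DrugRecord(pid, str(seq), "PS", name, name))
            seq += 1
        for _ in range(int(rng.poisson(config.concomitant_mean))):
            name = NON_STUDY_DRUGS[int(rng.integers(len(NON_STUDY_DRUGS)))]
            case_drugs.append(DrugRecord(pid, str(seq), "C", name, name))
            seq += 1
        drug.extend(case_drugs)

        # therapy dates for the primary suspect drug
        ther.append(
            TherRecord(
                primaryid=pid, dsg_drug_seq="1",
                start_dt=_full(start_date),
                end_dt=_full(event_date) if rng.random() < 0.5 else None,
            )
        )

        # reactions
        k = 1 + int(rng.poisson(config.ae_extra_mean))
        for j in rng.choice(len(pt_names), size=k, p=pt_prob_cache[g]):
            reac.append(ReacRecord(primaryid=pid, pt=pt_names[int(j)]))

        # outcomes (serious iff at least one code)
        if rng.random() < prof.serious_prob:
            codes = [c for c in OUTCOME_CODES if rng.random() < prof.outcome_probs.get(c, 0.0)]
            if not codes:
                codes = ["OT"]
            for c in codes:
                outc.append(OutcRecord(primaryid=pid, outc_cod=c))

        truth_rows.append(
            {"caseid": caseid, "group": g,
             "onset_days": float("nan") if onset_missing else onset}
        )

        # superseded earlier version: same case, earlier receipt date,
        # smaller primaryid — cleaning must remove exactly these
        if rng.random() < config.duplicate_rate:
            old_pid = caseid + "1"
            duplicate_pids.add(old_pid)
            demo.append(
                DemoRecord(
                    primaryid=old_pid, caseid=caseid,
                    fda_dt=_full(fda_date - _dt.timedelta(days=int(rng.integers(30, 181)))),
                    event_dt=event_dt, age=age, age_cod=age_cod, sex=sex,
                    occp_cod=occp, reporter_country=country, occr_country=country,
                )
            )
            for d in case_drugs:
                drug.append(DrugRecord(old_pid, d.drug_seq, d.role_cod, d.drugname, d.prod_ai))
            reac.append(ReacRecord(primaryid=old_pid, pt=pt_names[int(rng.choice(len(pt_names), p=pt_prob_cache[g]))]))

    caseids = [r["caseid"] for r in truth_rows]
    n_deleted = int(round(config.deleted_rate * n))
    deleted = set(
        np.random.default_rng(config.seed + 1).choice(caseids, size=n_deleted, replace=False)
    ) if n_deleted and caseids else set()

    pkg = faers_io.write_package(
        {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc, "THER": ther},
        directory,
        label="synthQ1",
        deleted_caseids=sorted(deleted),
    )
    truth = GroundTruth(
        cases=pd.DataFrame(truth_rows, columns=["caseid", "group", "onset_days"]),
        signals=pd.DataFrame(
            [{"group": s.group, "pt": s.pt, "multiplier": s.multiplier} for s in config.signal_spec],
            columns=["group", "pt", "multiplier"],
        ),
        duplicate_primaryids=duplicate_pids,
        deleted_caseids=deleted,
        pt_soc=pd.DataFrame(
            [{"pt_name": p.name, "soc_name": p.soc} for p in config.pt_vocab]
        ),
    )
    if write_truth:
        truth.write(directory)
    logger.info(
        "generated n_cases=%d demo_rows=%d reac_rows=%d duplicates=%d deleted=%d",
        n, len(demo), len(reac), len(duplicate_pids), len(deleted),
    )
    return pkg, truth


def expected_table(
    config: SyntheticConfig, group: str, pt: str
) -> tuple[float, float, float, float]:
    """Analytic expected fourfold cell counts (a, b, c, d) after cleaning.

    Expectation over the generative multinomials: surviving cases are
    n·(1−deleted_rate); each carries 1 + ae_extra_mean AE records on
    average; group g contributes weight w_g of cases and per-record PT
    probability from the renormalised multinomial. The comparator is
    the remaining five study groups (OTHER is outside the background).
    """
    config.validate()
    if group not in ALL_GROUPS or group == "OTHER":
        raise ValueError(f"unknown target group {group!r}")
    names = [p.name for p in config.pt_vocab]
    if pt not in names:
        raise ValueError(f"unknown PT {pt!r}")
    j = names.index(pt)
    mean_records = 1.0 + config.ae_extra_mean
    surviving = config.n_cases * (1.0 - config.deleted_rate)
    background = [g for g in ALL_GROUPS if g != "OTHER"]
    a = b = c = d = 0.0
    for g in background:
        records = surviving * config.group_weights.get(g, 0.0) * mean_records
        p = config.pt_probs(g)[j]
        if g == group:
            a, b = records * p, records * (1.0 - p)
        else:
            c += records * p
            d += records * (1.0 - p)
    return a, b, c, d
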
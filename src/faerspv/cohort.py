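"""Cohort construction and descriptive statistics.

Cases are assigned to study groups by their Primary Suspect (PS) drug:
four checkpoint-inhibitor monotherapies (ipilimumab, nivolumab,
durvalumab, tremelimumab), two dual-therapy combinations
(ipilimumab+nivolumab, durvalumab+tremelimumab), or OTHER. The four
monotherapy groups pooled form the single-agent arm (sICI); the two
combinations pooled form the dual-immunotherapy group (DIG). Baseline
tables cross-tabulate sICI vs DIG per variable with column percentages,
Cramér's V and a chi-square p-value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .faers_io import normalize_age
from .records import DemoRecord, DrugRecord, OutcRecord, PartialDate, TherRecord, days_between
from .records import OUTCOME_CODES

logger = logging.getLogger(__name__)

__all__ = [
    "STUDY_DRUGS",
    "MONO_GROUPS",
    "COMBO_GROUPS",
    "BACKGROUND_GROUPS",
    "DrugSynonymTable",
    "default_synonym_table",
    "load_synonym_table",
    "normalize_drug",
    "CohortAssignment",
    "assign_group",
    "assign_cohort",
    "CramersVResult",
    "cramers_v",
    "seriousness",
    "onset_time",
    "BaselineSummary",
    "baseline_summary",
    "country_counts",
    "AGE_BANDS",
    "ONSET_BANDS",
]

STUDY_DRUGS = ("ipilimumab", "nivolumab", "durvalumab", "tremelimumab")
MONO_GROUPS = {
    "ipilimumab": "IPI",
    "nivolumab": "NIVO",
    "durvalumab": "DURVA",
    "tremelimumab": "TREME",
}
COMBO_GROUPS = ("IPI_NIVO", "DURVA_TREME")
BACKGROUND_GROUPS = ("IPI", "NIVO", "DURVA", "TREME") + COMBO_GROUPS
SICI_GROUPS = frozenset(("IPI", "NIVO", "DURVA", "TREME"))
DIG_GROUPS = frozenset(COMBO_GROUPS)


@dataclass
class DrugSynonymTable:
    """Raw-name patterns mapped to the four canonical study drugs.

    Matching is case-insensitive substring search on trimmed text;
    longer patterns are tried first so brand-plus-strength strings
    resolve deterministically.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for pattern, canonical in self.entries:
            if canonical not in STUDY_DRUGS:
                raise ValueError(f"canonical drug {canonical!r} is not a study drug")
            if not pattern.strip():
                raise ValueError("empty synonym pattern")
        self.entries = sorted(
            ((p.strip().upper(), c) for p, c in self.entries),
            key=lambda e: (-len(e[0]), e[0]),
        )

    def match(self, text: Optional[str]) -> Optional[str]:
        if not text:
            return None
        hay = text.strip().upper()
        for pattern, canonical in self.entries:
            if pattern in hay:
                return canonical
        return None


def default_synonym_table() -> DrugSynonymTable:
    """Generic names plus US brand names of the four study drugs."""
    return DrugSynonymTable(
        entries=[
            ("IPILIMUMAB", "ipilimumab"),
            ("YERVOY", "ipilimumab"),
            ("NIVOLUMAB", "nivolumab"),
            ("OPDIVO", "nivolumab"),
            ("DURVALUMAB", "durvalumab"),
            ("IMFINZI", "durvalumab"),
            ("TREMELIMUMAB", "tremelimumab"),
            ("IMJUDO", "tremelimumab"),
        ]
    )


def load_synonym_table(path: str) -> DrugSynonymTable:
    """Load a 2-column TSV (pattern, canonical)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "pattern" not in cols or "canonical" not in cols:
        raise ValueError("synonym table needs columns: pattern, canonical")
    return DrugSynonymTable(entries=list(zip(df["pattern"], df["canonical"])))


def normalize_drug(
    raw_name: Optional[str],
    prod_ai: Optional[str],
    synonyms: DrugSynonymTable,
) -> Optional[str]:
    """Map a free-text drug name to a canonical study drug, or None.

    The verbatim drug name is tried first; the active-ingredient field
    is consulted only when the name does not match.
    """
    return synonyms.match(raw_name) or synonyms.match(prod_ai)


@dataclass(frozen=True)
class CohortAssignment:
    caseid: str
    group: str

    @property
    def is_background(self) -> bool:
        return self.group != "OTHER"


def assign_group(
    caseid: str, case_drugs: Sequence[DrugRecord], synonyms: DrugSynonymTable
) -> CohortAssignment:
    """Assign one case to its study group from its drug records.

    Let P be the canonical study drug(s) among PS-role records and S the
    canonical study drugs appearing with a suspect role (PS or SS).
    Monotherapy requires P = S = {one drug}; a combination requires the
    PS drug to be one partner and S exactly the partner pair. Everything
    else — non-study PS drug, three or more study drugs, no PS record —
    is OTHER.
    """
    ps_drugs: set[str] = set()
    suspect_drugs: set[str] = set()
    has_ps = False
    for rec in case_drugs:
        if rec.role_cod not in ("PS", "SS"):
            continue
        if rec.role_cod == "PS":
            has_ps = True
        canonical = normalize_drug(rec.drugname, rec.prod_ai, synonyms)
        if canonical is None:
            continue
        suspect_drugs.add(canonical)
        if rec.role_cod == "PS":
            ps_drugs.add(canonical)
    if not has_ps:
        logger.warning("case %s has no PS drug record; assigned OTHER", caseid)
        return CohortAssignment(caseid, "OTHER")
    if not ps_drugs:
        return CohortAssignment(caseid, "OTHER")
    if len(suspect_drugs) == 1 and len(ps_drugs) == 1:
        (drug,) = suspect_drugs
        if ps_drugs == suspect_drugs:
            return CohortAssignment(caseid, MONO_GROUPS[drug])
    if suspect_drugs == {"ipilimumab", "nivolumab"} and ps_drugs <= suspect_drugs:
        return CohortAssignment(caseid, "IPI_NIVO")
    if suspect_drugs == {"durvalumab", "tremelimumab"} and ps_drugs <= suspect_drugs:
        return CohortAssignment(caseid, "DURVA_TREME")
    return CohortAssignment(caseid, "OTHER")


def assign_cohort(
    demo_records: Sequence[DemoRecord],
    drug_records: Sequence[DrugRecord],
    synonyms: Optional[DrugSynonymTable] = None,
) -> list[CohortAssignment]:
    """Assign every cleaned case, joining drugs on primaryid."""
    synonyms = synonyms or default_synonym_table()
    by_pid: dict[str, list[DrugRecord]] = {}
    for rec in drug_records:
        by_pid.setdefault(rec.primaryid, []).append(rec)
    out = []
    n_both_ps = 0
    for demo in demo_records:
        drugs = by_pid.get(demo.primaryid, [])
        a = assign_group(demo.caseid, drugs, synonyms)
        if a.group in COMBO_GROUPS:
            ps = {
                normalize_drug(d.drugname, d.prod_ai, synonyms)
                for d in drugs
                if d.role_cod == "PS"
            }
            if len(ps - {None}) == 2:
                n_both_ps += 1
        out.append(a)
    logger.info(
        "stage=assign_cohort in=%d background=%d combos_with_both_drugs_ps=%d",
        len(demo_records),
        sum(a.is_background for a in out),
        n_both_ps,
    )
    return out


# ---------------------------------------------------------------------------
# association statistics


@dataclass(frozen=True)
class CramersVResult:
    chi2: float
    v: float
    p: float
    dof: int


def cramers_v(table) -> CramersVResult:
    """Cramér's V with Pearson chi-square (no continuity correction).

    V = sqrt(chi2 / (N * (min(r, c) - 1))). Zero rows/columns are
    dropped with a warning before computing; a table degenerate after
    dropping (fewer than 2 rows or columns) raises ValueError.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    row_ok = arr.sum(axis=1) > 0
    col_ok = arr.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("dropping %d zero rows / %d zero columns", (~row_ok).sum(), (~col_ok).sum())
        arr = arr[row_ok][:, col_ok]
    r, c = arr.shape
    if r < 2 or c < 2:
        raise ValueError("degenerate table: need at least 2 non-empty rows and columns")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    n = arr.sum()
    v = math.sqrt(chi2 / (n * (min(r, c) - 1)))
    return CramersVResult(chi2=float(chi2), v=float(v), p=float(p), dof=int(dof))


def seriousness(outc_records: Sequence[OutcRecord]) -> tuple[bool, dict[str, bool]]:
    """A report is serious iff it carries at least one outcome code."""
    codes = {r.outc_cod for r in outc_records}
    flags = {code: code in codes for code in OUTCOME_CODES}
    return bool(codes), flags


def onset_time(
    demo: DemoRecord,
    case_drugs: Sequence[DrugRecord],
    case_ther: Sequence[TherRecord],
) -> tuple[Optional[int], bool]:
    """Days from earliest PS-drug therapy start to the event date.

    Returns (days, negative_flag). Missing unless the event date and at
    least one linked PS therapy start date are full calendar dates.
    Negative onsets (event before recorded start) are returned and
    flagged; banding decides their fate downstream.
    """
    if demo.event_dt is None or not demo.event_dt.is_full:
        return None, False
    ps_seqs = {d.drug_seq for d in case_drugs if d.role_cod == "PS"}
    starts = [
        t.start_dt
        for t in case_ther
        if t.dsg_drug_seq in ps_seqs and t.start_dt is not None and t.start_dt.is_full
    ]
    if not starts:
        return None, False
    earliest = min(starts, key=PartialDate.sort_key)
    delta = days_between(earliest, demo.event_dt)
    return delta, (delta is not None and delta < 0)


# ---------------------------------------------------------------------------
# baseline summary (Table-2-style)

AGE_BANDS = [
    ("<18", 0.0, 18.0),
    ("18-44", 18.0, 45.0),
    ("45-64", 45.0, 65.0),
    ("65-74", 65.0, 75.0),
    (">=75", 75.0, math.inf),
]

ONSET_BANDS = [
    ("<30 days", 0, 30),
    ("31-60 days", 31, 60),
    ("61-90 days", 61, 90),
    ("91-120 days", 91, 120),
    ("121-150 days", 121, 150),
    ("151-180 days", 151, 180),
    ("181-360 days", 181, 360),
    (">360 days", 361, 10**9),
]

OCCP_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "OT": "Other health-professional",
    "CN": "Consumer",
    "LW": "Lawyer",
}


def _age_band(years: Optional[float]) -> str:
    if years is None:
        return "Unspecified"
    for label, lo, hi in AGE_BANDS:
        if lo <= years < hi:
            return label
    return "Unspecified"


def _onset_band(days: Optional[int], mode: str) -> str:
    if days is None:
        return "Missing"
    if days < 0:
        # inclusive mode folds negative onsets into the lowest band;
        # strict mode drops them from the banded view
        return "<30 days" if mode == "inclusive" else "Missing"
    for label, lo, hi in ONSET_BANDS:
        if lo <= days <= hi:
            return label
    return "Missing"


@dataclass
class BaselineSummary:
    """Per-variable sICI-vs-DIG cross-tabulations plus quantitative blocks.

    ``tables[variable]`` is a DataFrame with category rows and columns
    (sICI, DIG, sICI_pct, DIG_pct); ``stats[variable]`` holds the
    matching Cramér's V result. ``quantitative`` maps block name to a
    dict of N/missing/mean/sd/median/q1/q3/min/max per column.
    """

    n_sici: int
    n_dig: int
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    stats: dict[str, CramersVResult] = field(default_factory=dict)
    quantitative: dict[str, pd.DataFrame] = field(default_factory=dict)
    per_group_tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to one tidy frame (variable, category, counts, pct, V, p)."""
        rows = []
        for var, tab in self.tables.items():
            st = self.stats.get(var)
            for cat, row in tab.iterrows():
                rows.append(
                    {
                        "variable": var,
                        "category": cat,
                        "sici_n": int(row["sICI"]),
                        "dig_n": int(row["DIG"]),
                        "sici_pct": row["sICI_pct"],
                        "dig_pct": row["DIG_pct"],
                        "cramers_v": st.v if st else np.nan,
                        "p": st.p if st else np.nan,
                    }
                )
        return pd.DataFrame(rows)


def _crosstab(cat: pd.Series, pool: pd.Series, order: Sequence[str]) -> pd.DataFrame:
    tab = pd.crosstab(cat, pool).reindex(index=list(order), columns=["sICI", "DIG"]).fillna(0)
    tab = tab.astype(int)
    out = tab.copy()
    for col in ("sICI", "DIG"):
        total = tab[col].sum()
        out[f"{col}_pct"] = 100.0 * tab[col] / total if total else 0.0
    return out


def _quant_block(values: Mapping[str, pd.Series], n_total: Mapping[str, int]) -> pd.DataFrame:
    rows = {}
    for col, s in values.items():
        s = s.dropna().astype(float)
        rows[col] = {
            "n": len(s),
            "missing": n_total[col] - len(s),
            "mean": s.mean() if len(s) else np.nan,
            "sd": s.std(ddof=1) if len(s) > 1 else np.nan,
            "median": s.median() if len(s) else np.nan,
            "q1": s.quantile(0.25) if len(s) else np.nan,
            "q3": s.quantile(0.75) if len(s) else np.nan,
            "min": s.min() if len(s) else np.nan,
            "max": s.max() if len(s) else np.nan,
        }
    return pd.DataFrame(rows)


def baseline_summary(
    assignments: Sequence[CohortAssignment],
    demo_records: Sequence[DemoRecord],
    outc_records: Sequence[OutcRecord],
    ther_records: Sequence[TherRecord],
    drug_records: Sequence[DrugRecord],
    onset_mode: str = "inclusive",
) -> BaselineSummary:
    """Tabulate every baseline variable for the pooled sICI vs DIG arms.

    Patient level: one row per case. Variables with a degenerate
    cross-tabulation (all counts in one column) carry no V/p.
    """
    if onset_mode not in ("inclusive", "strict"):
        raise ValueError("onset_mode must be 'inclusive' or 'strict'")
    group_of = {a.caseid: a.group for a in assignments if a.is_background}
    demo = [r for r in demo_records if r.caseid in group_of]
    pids = {r.primaryid for r in demo}
    outc_by_pid: dict[str, list[OutcRecord]] = {}
    for r in outc_records:
        if r.primaryid in pids:
            outc_by_pid.setdefault(r.primaryid, []).append(r)
    drug_by_pid: dict[str, list[DrugRecord]] = {}
    for r in drug_records:
        if r.primaryid in pids:
            drug_by_pid.setdefault(r.primaryid, []).append(r)
    ther_by_pid: dict[str, list[TherRecord]] = {}
    for r in ther_records:
        if r.primaryid in pids:
            ther_by_pid.setdefault(r.primaryid, []).append(r)

    rows = []
    for r in demo:
        group = group_of[r.caseid]
        pool = "sICI" if group in SICI_GROUPS else "DIG"
        serious, flags = seriousness(outc_by_pid.get(r.primaryid, []))
        onset, _neg = onset_time(r, drug_by_pid.get(r.primaryid, []), ther_by_pid.get(r.primaryid, []))
        age_years = normalize_age(r.age, r.age_cod)
        rows.append(
            {
                "caseid": r.caseid,
                "group": group,
                "pool": pool,
                "sex": r.sex or "Unspecified",
                "age_years": age_years,
                "age_band": _age_band(age_years),
                "year": r.fda_dt.year,
                "occupation": OCCP_LABELS.get(r.occp_cod or "", "Unspecified"),
                "serious": "Serious" if serious else "Non-Serious",
                **{f"outc_{c}": "Yes" if flags[c] else "No" for c in OUTCOME_CODES},
                "onset_days": onset,
                "onset_band": _onset_band(onset, onset_mode),
            }
        )
    df = pd.DataFrame(rows)
    summary = BaselineSummary(
        n_sici=int((df["pool"] == "sICI").sum()) if len(df) else 0,
        n_dig=int((df["pool"] == "DIG").sum()) if len(df) else 0,
    )
    if df.empty:
        return summary

    sex_order = ["F", "M", "Unspecified"]
    age_order = [b[0] for b in AGE_BANDS] + ["Unspecified"]
    year_order = [str(y) for y in sorted(df["year"].unique())]
    occ_order = sorted(df["occupation"].unique())
    onset_order = [b[0] for b in ONSET_BANDS] + ["Missing"]

    spec = {
        "sex": (df["sex"], sex_order),
        "age_band": (df["age_band"], age_order),
        "reporting_year": (df["year"].astype(str), year_order),
        "occupation": (df["occupation"], occ_order),
        "serious": (df["serious"], ["Serious", "Non-Serious"]),
        **{
            f"outcome_{c}": (df[f"outc_{c}"], ["Yes", "No"])
            for c in OUTCOME_CODES
        },
        "onset_band": (df["onset_band"], onset_order),
    }
    for var, (series, order) in spec.items():
        tab = _crosstab(series, df["pool"], order)
        summary.tables[var] = tab
        counts = tab[["sICI", "DIG"]].to_numpy()
        try:
            summary.stats[var] = cramers_v(counts)
        except ValueError:
            logger.warning("variable %s degenerate; no association statistic", var)

    n_per_pool = {"sICI": summary.n_sici, "DIG": summary.n_dig}
    n_per_pool["Total"] = summary.n_sici + summary.n_dig
    for name, col in (("age_years", "age_years"), ("onset_days", "onset_days")):
        vals = {
            "sICI": df.loc[df["pool"] == "sICI", col],
            "DIG": df.loc[df["pool"] == "DIG", col],
            "Total": df[col],
        }
        summary.quantitative[name] = _quant_block(vals, n_per_pool)

    # per-subgroup counts (the six-group analogue of the pooled table)
    for var, (series, order) in spec.items():
        summary.per_group_tables[var] = (
            pd.crosstab(series, df["group"])
            .reindex(index=list(order), columns=list(BACKGROUND_GROUPS))
            .fillna(0)
            .astype(int)
        )
    return summary


def country_counts(
    demo_records: Sequence[DemoRecord],
    background_caseids: Optional[Iterable[str]] = None,
) -> pd.Series:
    """Cases per occurrence country, falling back to reporter country.

    Sorted descending; missing both countries groups under "UNKNOWN".
    """
    keep = set(background_caseids) if background_caseids is not None else None
    counts: dict[str, int] = {}
    for r in demo_records:
        if keep is not None and r.caseid not in keep:
            continue
        country = r.occr_country or r.reporter_country or "UNKNOWN"
        counts[country] = counts.get(country, 0) + 1
    s = pd.Series(counts, dtype=int).sort_values(ascending=False, kind="stable")
    s.name = "n_cases"
    s.index.name = "country"
    return s
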
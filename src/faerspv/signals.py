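"""Disproportionality signal detection: ROR and BCPNN information component.

Counting is at the adverse-event-record level: each REAC row of a
background case is one unit. For a target group g and preferred term t,
the fourfold table is

    a = records of t in g          b = other records in g
    c = records of t elsewhere     d = other records elsewhere

with "elsewhere" the remaining background groups (case vs non-case
within the study background, not all of FAERS).

Two detectors run on each table:

* ROR = (a·d)/(b·c) with the log-scale Wald 95% interval
  exp(ln ROR ± 1.96·sqrt(1/a+1/b+1/c+1/d)); any zero cell triggers the
  Haldane +0.5 correction and a flag.
* The information component IC = log2 of the shrunken observed/expected
  reporting ratio. The default estimator puts a gamma posterior on the
  Poisson rate: with E = (a+b)(a+c)/N,

      IC      = log2((a + 0.5) / (E + 0.5))
      IC_025  = log2( Gamma(shape=a+0.5, rate=E+0.5).ppf(0.025) )

  The closed-form BCPNN of Bate et al. (posterior mean and variance of
  IC under priors centred on independence, IC_025 = E[IC] − 1.96·sd) is
  selectable via ``variant="bate"``.

A pair is a positive signal only when both detectors fire and the
count criterion holds: a ≥ 3, ROR_025 > 1 and IC_025 > 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import BACKGROUND_GROUPS, CohortAssignment
from .records import ReacRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "build_tables",
    "ror",
    "ic",
    "signal_flag",
    "fdr_adjust",
    "pt_p_value",
    "screen_group",
    "screen_all_groups",
    "ic025_matrix",
]

Z_95 = 1.96  # fixed normal quantile for the 95% Wald interval


@dataclass(frozen=True)
class ContingencyTable:
    group: str
    pt: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        return (self.a + self.b) * (self.a + self.c) / self.n

    @property
    def degenerate(self) -> bool:
        """True when the comparator side is empty (single-group background)."""
        return self.c + self.d == 0


@dataclass
class SignalResult:
    group: str
    pt: str
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_025: float
    ror_975: float
    ic: float
    ic_025: float
    p_raw: float
    p_method: str
    p_fdr: float = math.nan
    positive: bool = False
    haldane: bool = False


def build_tables(
    reac_records: Sequence[ReacRecord],
    assignments: Sequence[CohortAssignment],
    demo_records,
    target_group: str,
) -> dict[str, ContingencyTable]:
    """Fourfold tables for every PT observed in the target group.

    ``demo_records`` supplies the primaryid→caseid link; only
    background cases (the six study groups) contribute records.
    """
    if target_group not in BACKGROUND_GROUPS:
        raise ValueError(f"unknown group {target_group!r}")
    group_of_case = {a.caseid: a.group for a in assignments if a.is_background}
    group_of_pid = {
        r.primaryid: group_of_case[r.caseid] for r in demo_records if r.caseid in group_of_case
    }
    in_target: dict[str, int] = {}
    elsewhere: dict[str, int] = {}
    n_target = 0
    n_elsewhere = 0
    for rec in reac_records:
        g = group_of_pid.get(rec.primaryid)
        if g is None:
            continue
        pt = rec.pt.strip().lower()
        if g == target_group:
            in_target[pt] = in_target.get(pt, 0) + 1
            n_target += 1
        else:
            elsewhere[pt] = elsewhere.get(pt, 0) + 1
            n_elsewhere += 1
    if n_target == 0:
        logger.warning("target group %s has no AE records", target_group)
        return {}
    tables = {}
    for pt, a in in_target.items():
        c = elsewhere.get(pt, 0)
        tbl = ContingencyTable(
            group=target_group, pt=pt, a=a, b=n_target - a, c=c, d=n_elsewhere - c
        )
        if tbl.degenerate:
            logger.warning("single-group background: table for %r has empty comparator", pt)
        tables[pt] = tbl
    return tables


def ror(table: ContingencyTable) -> tuple[float, float, float, bool]:
    """Reporting odds ratio with 95% CI; returns (ror, lo, hi, haldane).

    Zero cells get the Haldane +0.5 correction (flagged). A table with
    no information at all (a+b or c+d empty after correction cannot
    happen; an all-zero table is rejected upstream) — a fully
    uninformative ratio yields NaNs.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    haldane = min(a, b, c, d) == 0.0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if min(a, b, c, d) <= 0:  # pragma: no cover - unreachable after correction
        return math.nan, math.nan, math.nan, haldane
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(estimate) - Z_95 * se)
    hi = math.exp(math.log(estimate) + Z_95 * se)
    return estimate, lo, hi, haldane


def _ic_gamma(a: int, expected: float) -> tuple[float, float]:
    point = math.log2((a + 0.5) / (expected + 0.5))
    q = stats.gamma.ppf(0.025, a + 0.5, scale=1.0 / (expected + 0.5))
    return point, math.log2(q)


def _ic_bate(a: int, row1: int, col1: int, n: int) -> tuple[float, float]:
    # closed-form posterior moments of IC with priors centred on
    # independence: gamma11=1, alpha1=beta1=1, alpha=beta=2
    g11, a1, b1, al, be = 1.0, 1.0, 1.0, 2.0, 2.0
    gamma = g11 * (n + al) * (n + be) / ((row1 + a1) * (col1 + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + gamma) * (row1 + a1) * (col1 + b1))
    )
    ln2sq = math.log(2.0) ** 2
    v_ic = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - row1 + al - a1) / ((row1 + a1) * (1 + n + al))
        + (n - col1 + be - b1) / ((col1 + b1) * (1 + n + be))
    ) / ln2sq
    return e_ic, e_ic - Z_95 * math.sqrt(v_ic)


def ic(table: ContingencyTable, variant: str = "gamma") -> tuple[float, float]:
    """Information component and its 2.5% lower bound, in bits.

    ``variant="gamma"`` (default) is the gamma-posterior shrinkage
    estimator; ``variant="bate"`` the closed-form BCPNN approximation.
    a = 0 is allowed (deep negative IC) and flagged in the log.
    """
    if variant not in ("gamma", "bate"):
        raise ValueError(f"unknown IC variant {variant!r}")
    if table.a == 0:
        logger.debug("IC computed with a=0 for (%s, %s)", table.group, table.pt)
    if variant == "gamma":
        return _ic_gamma(table.a, table.expected_a)
    return _ic_bate(table.a, table.a + table.b, table.a + table.c, table.n)


def signal_flag(a: int, ror_025: float, ic_025: float) -> bool:
    """Joint positivity: a ≥ 3 and ROR_025 > 1 and IC_025 > 0.

    Non-computable (NaN) components never produce a positive flag.
    """
    if not (np.isfinite(ror_025) and np.isfinite(ic_025)):
        return False
    return a >= 3 and ror_025 > 1.0 and ic_025 > 0.0


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pt_p_value(table: ContingencyTable) -> tuple[float, str]:
    """Independence p for one fourfold table.

    Pearson chi-square without continuity correction; Fisher's exact
    (two-sided) when any expected cell is below 5. Degenerate margins
    give p = 1 with method "degenerate".
    """
    arr = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0, "degenerate"
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected < 5).any():
        _, p = stats.fisher_exact(arr.astype(int), alternative="two-sided")
        return float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(p), "chi2"


def screen_group(
    tables: Mapping[str, ContingencyTable], variant: str = "gamma"
) -> pd.DataFrame:
    """Run both detectors over one group's tables; one FDR family per group.

    Returns a frame sorted by descending a with columns pt, a..d, ror,
    ror_025, ror_975, ic, ic_025, p_raw, p_method, p_fdr, positive,
    haldane.
    """
    results: list[SignalResult] = []
    for pt in sorted(tables):
        t = tables[pt]
        r, lo, hi, haldane = ror(t)
        point, lower = ic(t, variant=variant)
        p_raw, method = pt_p_value(t)
        results.append(
            SignalResult(
                group=t.group,
                pt=pt,
                a=t.a,
                b=t.b,
                c=t.c,
                d=t.d,
                ror=r,
                ror_025=lo,
                ror_975=hi,
                ic=point,
                ic_025=lower,
                p_raw=p_raw,
                p_method=method,
                positive=signal_flag(t.a, lo, lower),
                haldane=haldane,
            )
        )
    if results:
        adjusted = fdr_adjust([r.p_raw for r in results])
        for r, p in zip(results, adjusted):
            r.p_fdr = float(p)
    columns = [
        "group", "pt", "a", "b", "c", "d", "ror", "ror_025", "ror_975",
        "ic", "ic_025", "p_raw", "p_method", "p_fdr", "positive", "haldane",
    ]
    df = pd.DataFrame([vars(r) for r in results], columns=columns)
    if not df.empty:
        df = df.sort_values(["a", "pt"], ascending=[False, True], kind="stable").reset_index(
            drop=True
        )
    return df


def screen_all_groups(
    reac_records: Sequence[ReacRecord],
    assignments: Sequence[CohortAssignment],
    demo_records,
    groups: Sequence[str] = BACKGROUND_GROUPS,
    variant: str = "gamma",
) -> dict[str, pd.DataFrame]:
    """Signal screen per group against the rest of the study background."""
    out = {}
    for g in groups:
        tables = build_tables(reac_records, assignments, demo_records, g)
        out[g] = screen_group(tables, variant=variant)
    return out


def ic025_matrix(screens: Mapping[str, pd.DataFrame], min_a: int = 0) -> pd.DataFrame:
    """Wide PT × group matrix of IC_025 values (heatmap-ready).

    ``min_a`` restricts rows to PTs reaching that count in at least one
    group (the display threshold used for report figures).
    """
    pieces = []
    for g, df in screens.items():
        if df.empty:
            continue
        pieces.append(df[["pt", "a", "ic_025"]].assign(group=g))
    if not pieces:
        return pd.DataFrame()
    tall = pd.concat(pieces, ignore_index=True)
    keep = tall.groupby("pt")["a"].max()
    tall = tall[tall["pt"].isin(keep[keep >= min_a].index)]
    return tall.pivot_table(index="pt", columns="group", values="ic_025", aggfunc="first")
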
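"""Typed records for the FAERS quarterly ASCII tables.

FAERS distributes each quarter as "$"-delimited text tables. The five
tables this package consumes are DEMO (one row per report version),
DRUG, REAC, OUTC and THER (one-to-many per report). Reports are
versioned: a case (CASEID) may appear under several PRIMARYIDs across
quarters, and dates are frequently partial (YYYY or YYYYMM).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "PartialDate",
    "DemoRecord",
    "DrugRecord",
    "ReacRecord",
    "OutcRecord",
    "TherRecord",
    "QuarterlyPackage",
    "ROLE_CODES",
    "OUTCOME_CODES",
    "AGE_CODES",
]

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")
AGE_CODES = frozenset({"DEC", "YR", "MON", "WK", "DY", "HR"})


@dataclass(frozen=True)
class PartialDate:
    """A FAERS date: year always present, month/day optional.

    Partial dates take part in year tabulations and in ordering (missing
    components sort before any filled component of the same prefix) but
    compare as missing for day arithmetic.
    """

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if not (1900 <= self.year <= 2200):
            raise ValueError(f"implausible year {self.year}")
        if self.month is not None and not (1 <= self.month <= 12):
            raise ValueError(f"bad month {self.month}")
        if self.day is not None:
            if self.month is None:
                raise ValueError("day without month")
            if not (1 <= self.day <= 31):
                raise ValueError(f"bad day {self.day}")

    @property
    def is_full(self) -> bool:
        return self.month is not None and self.day is not None

    def sort_key(self) -> tuple[int, int, int]:
        # missing components count as 0: a partial date orders before any
        # full date sharing its prefix (deterministic total order only)
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> Optional[_dt.date]:
        """Calendar date, or None when the date is partial."""
        if not self.is_full:
            return None
        return _dt.date(self.year, self.month, self.day)

    @classmethod
    def parse(cls, text: str) -> Optional["PartialDate"]:
        """Parse YYYY, YYYYMM or YYYYMMDD; empty/invalid -> None."""
        text = text.strip()
        if not text or not text.isdigit():
            return None
        try:
            if len(text) == 4:
                return cls(int(text))
            if len(text) == 6:
                return cls(int(text[:4]), int(text[4:6]))
            if len(text) == 8:
                return cls(int(text[:4]), int(text[4:6]), int(text[6:8]))
        except ValueError:
            return None
        return None

    def __str__(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


def days_between(start: Optional[PartialDate], end: Optional[PartialDate]) -> Optional[int]:
    """end - start in days; None unless both dates are full."""
    if start is None or end is None:
        return None
    a, b = start.to_date(), end.to_date()
    if a is None or b is None:
        return None
    return (b - a).days


@dataclass(frozen=True)
class DemoRecord:
    primaryid: str
    caseid: str
    fda_dt: PartialDate
    event_dt: Optional[PartialDate] = None
    age: Optional[float] = None
    age_cod: Optional[str] = None
    sex: Optional[str] = None
    occp_cod: Optional[str] = None
    reporter_country: Optional[str] = None
    occr_country: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.primaryid or not self.caseid:
            raise ValueError("primaryid and caseid must be non-empty")


@dataclass(frozen=True)
class DrugRecord:
    primaryid: str
    drug_seq: str
    role_cod: str
    drugname: str
    prod_ai: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role_cod not in ROLE_CODES:
            raise ValueError(f"unknown role_cod {self.role_cod!r}")


@dataclass(frozen=True)
class ReacRecord:
    primaryid: str
    pt: str

    def __post_init__(self) -> None:
        if not self.pt.strip():
            raise ValueError("empty PT")


@dataclass(frozen=True)
class OutcRecord:
    primaryid: str
    outc_cod: str

    def __post_init__(self) -> None:
        if self.outc_cod not in OUTCOME_CODES:
            raise ValueError(f"unknown outc_cod {self.outc_cod!r}")


@dataclass(frozen=True)
class TherRecord:
    primaryid: str
    dsg_drug_seq: str
    start_dt: Optional[PartialDate] = None
    end_dt: Optional[PartialDate] = None

    @property
    def end_before_start(self) -> bool:
        """True when both dates are full and end precedes start.

        Real quarters contain such rows; they are flagged, never dropped.
        """
        d = days_between(self.start_dt, self.end_dt)
        return d is not None and d < 0


@dataclass
class QuarterlyPackage:
    """Paths making up one quarterly ASCII package.

    DEMO, DRUG and REAC are mandatory; OUTC, THER and the deleted-case
    list may be absent (quarters before 2019Q1 ship no deletion list)
    and then contribute empty record sets.
    """

    label: str
    table_paths: dict = field(default_factory=dict)
    deleted_list_path: Optional[str] = None

    MANDATORY = ("DEMO", "DRUG", "REAC")

    def validate(self) -> None:
        import os

        for name in self.MANDATORY:
            p = self.table_paths.get(name)
            if p is None or not os.path.exists(p):
                raise FileNotFoundError(f"package {self.label}: missing mandatory table {name}")
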
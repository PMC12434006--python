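"""Reader and writer for the FAERS quarterly "$"-delimited ASCII dialect.

The dialect is one header line of column names, then one "$"-separated
row per record, with no quoting or escape mechanism. Column names are
matched case-insensitively and extra columns are ignored (header casing
and trailing columns vary across quarters). Files are decoded as UTF-8
with a Latin-1 fallback.

Parsing never invents or silently discards data: every data line either
yields a record or increments the malformed counter, so
``len(records) + n_malformed == number of data lines``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .records import (
    AGE_CODES,
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
    "ParseResult",
    "parse_table",
    "load_deleted_cases",
    "normalize_age",
    "write_package",
    "read_package",
    "TABLE_COLUMNS",
    "SchemaError",
]

DELIM = "$"

# canonical column order used by the writer; the parser accepts any order
TABLE_COLUMNS = {
    "DEMO": [
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "age",
        "age_cod",
        "sex",
        "occp_cod",
        "reporter_country",
        "occr_country",
    ],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"],
}

MANDATORY_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt"],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "THER": ["primaryid", "dsg_drug_seq"],
}


class SchemaError(ValueError):
    """Header is missing a mandatory column."""


@dataclass
class ParseResult:
    """Records plus a full accounting of the lines seen."""

    table_name: str
    records: list = field(default_factory=list)
    n_malformed: int = 0
    n_data_lines: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _read_lines(path: str) -> list[str]:
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    return text.splitlines()


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def normalize_age(age: Optional[float], age_cod: Optional[str]) -> Optional[float]:
    """Convert a FAERS (AGE, AGE_COD) pair to years.

    DEC is decades, YR years, MON months, WK weeks, DY days, HR hours.
    A missing unit code with age present is read as years (the dominant
    FAERS convention). Negative ages are not interpretable and map to
    missing with a warning.
    """
    if age is None:
        return None
    if age < 0:
        logger.warning("negative age %s treated as missing", age)
        return None
    code = (age_cod or "YR").strip().upper() or "YR"
    factors = {
        "DEC": 10.0,
        "YR": 1.0,
        "MON": 1.0 / 12.0,
        "WK": 1.0 / 52.0,
        "DY": 1.0 / 365.25,
        "HR": 1.0 / 8766.0,
    }
    if code not in factors:
        logger.warning("unknown age code %r treated as years", age_cod)
        code = "YR"
    return age * factors[code]


def _build_demo(get) -> DemoRecord:
    fda = PartialDate.parse(get("fda_dt") or "")
    if fda is None:
        raise ValueError("unparseable fda_dt")
    age_txt = _opt(get("age") or "")
    age = None
    if age_txt is not None:
        age = float(age_txt)  # ValueError -> malformed
    age_cod = _opt((get("age_cod") or "").upper())
    if age_cod is not None and age_cod not in AGE_CODES:
        raise ValueError(f"unknown age_cod {age_cod!r}")
    sex = _opt((get("sex") or "").upper())
    return DemoRecord(
        primaryid=(get("primaryid") or "").strip(),
        caseid=(get("caseid") or "").strip(),
        fda_dt=fda,
        event_dt=PartialDate.parse(get("event_dt") or ""),
        age=age,
        age_cod=age_cod,
        sex=sex if sex in ("F", "M") else None,
        occp_cod=_opt((get("occp_cod") or "").upper()),
        reporter_country=_opt(get("reporter_country") or ""),
        occr_country=_opt(get("occr_country") or ""),
    )


def _build_drug(get) -> DrugRecord:
    return DrugRecord(
        primaryid=(get("primaryid") or "").strip(),
        drug_seq=(get("drug_seq") or "").strip(),
        role_cod=(get("role_cod") or "").strip().upper(),
        drugname=(get("drugname") or "").strip(),
        prod_ai=_opt(get("prod_ai") or ""),
    )


def _build_reac(get) -> ReacRecord:
    return ReacRecord(
        primaryid=(get("primaryid") or "").strip(),
        pt=(get("pt") or "").strip(),
    )


def _build_outc(get) -> OutcRecord:
    return OutcRecord(
        primaryid=(get("primaryid") or "").strip(),
        outc_cod=(get("outc_cod") or "").strip().upper(),
    )


def _build_ther(get) -> TherRecord:
    rec = TherRecord(
        primaryid=(get("primaryid") or "").strip(),
        dsg_drug_seq=(get("dsg_drug_seq") or "").strip(),
        start_dt=PartialDate.parse(get("start_dt") or ""),
        end_dt=PartialDate.parse(get("end_dt") or ""),
    )
    if rec.end_before_start:
        logger.warning("therapy end before start for primaryid %s (kept)", rec.primaryid)
    return rec


_BUILDERS = {
    "DEMO": _build_demo,
    "DRUG": _build_drug,
    "REAC": _build_reac,
    "OUTC": _build_outc,
    "THER": _build_ther,
}


def parse_table(path: str, table_name: str) -> ParseResult:
    """Parse one FAERS ASCII table into typed records.

    Raises ``SchemaError`` when a mandatory column is absent from the
    header. Lines with the wrong field count or uninterpretable
    mandatory fields are counted as malformed, never silently dropped.
    """
    table_name = table_name.upper()
    if table_name not in _BUILDERS:
        raise ValueError(f"unknown table {table_name!r}")
    lines = _read_lines(path)
    if not lines:
        raise SchemaError(f"{path}: empty file, no header")
    header = [c.strip().lower() for c in lines[0].split(DELIM)]
    for col in MANDATORY_COLUMNS[table_name]:
        if col not in header:
            raise SchemaError(f"{path}: header lacks mandatory column {col!r}")
    index = {c: i for i, c in enumerate(header)}
    build = _BUILDERS[table_name]

    result = ParseResult(table_name=table_name)
    for line in lines[1:]:
        if line.strip() == "":
            continue
        result.n_data_lines += 1
        fields = line.split(DELIM)
        if len(fields) != len(header):
            result.n_malformed += 1
            continue

        def get(col: str, _fields=fields) -> Optional[str]:
            i = index.get(col)
            return _fields[i] if i is not None else None

        try:
            result.records.append(build(get))
        except (ValueError, TypeError):
            result.n_malformed += 1
    if result.n_malformed:
        logger.warning(
            "%s: %d of %d data lines malformed", path, result.n_malformed, result.n_data_lines
        )
    return result


def load_deleted_cases(path: Optional[str]) -> set[str]:
    """Read a deleted-case list (one CASEID per line, header tolerated).

    A missing file yields an empty set with a warning: quarters before
    2019Q1 ship no deletion list.
    """
    if path is None or not os.path.exists(path):
        logger.warning("deleted-case list %s absent; treating as empty", path)
        return set()
    out: set[str] = set()
    for i, line in enumerate(_read_lines(path)):
        token = line.strip().split(DELIM)[0].strip()
        if not token:
            continue
        if i == 0 and not token.isdigit() and token.lower() in ("caseid", "case_id"):
            continue
        out.add(token)
    return out


def _sanitize(text: str) -> str:
    # the dialect has no escape mechanism: embedded delimiters and
    # newlines in free text are replaced, and the round-trip preserves
    # the sanitized form
    return text.replace(DELIM, "/").replace("\n", " ").replace("\r", " ")


def _demo_row(r: DemoRecord) -> list[str]:
    return [
        r.primaryid,
        r.caseid,
        str(r.fda_dt),
        str(r.event_dt) if r.event_dt else "",
        ("%g" % r.age) if r.age is not None else "",
        r.age_cod or "",
        r.sex or "",
        r.occp_cod or "",
        r.reporter_country or "",
        r.occr_country or "",
    ]


def _drug_row(r: DrugRecord) -> list[str]:
    return [r.primaryid, r.drug_seq, r.role_cod, r.drugname, r.prod_ai or ""]


def _reac_row(r: ReacRecord) -> list[str]:
    return [r.primaryid, r.pt]


def _outc_row(r: OutcRecord) -> list[str]:
    return [r.primaryid, r.outc_cod]


def _ther_row(r: TherRecord) -> list[str]:
    return [
        r.primaryid,
        r.dsg_drug_seq,
        str(r.start_dt) if r.start_dt else "",
        str(r.end_dt) if r.end_dt else "",
    ]


_ROW_WRITERS = {
    "DEMO": _demo_row,
    "DRUG": _drug_row,
    "REAC": _reac_row,
    "OUTC": _outc_row,
    "THER": _ther_row,
}


def write_package(
    tables: dict[str, Sequence],
    directory: str,
    label: str = "synthetic",
    deleted_caseids: Optional[Sequence[str]] = None,
) -> QuarterlyPackage:
    """Write records back out in the exact FAERS dialect.

    ``tables`` maps table names to record sequences; absent OUTC/THER
    entries produce header-only files so the package always re-parses.
    Round-trip: ``parse_table(write_package(x))`` reproduces every field.
    """
    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    for name, columns in TABLE_COLUMNS.items():
        records = tables.get(name, [])
        path = os.path.join(directory, f"{name}{label}.txt")
        writer = _ROW_WRITERS[name]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(DELIM.join(columns) + "\n")
            for rec in records:
                fh.write(DELIM.join(_sanitize(f) for f in writer(rec)) + "\n")
        paths[name] = path
    deleted_path = None
    if deleted_caseids is not None:
        deleted_path = os.path.join(directory, f"DELETED{label}.txt")
        with open(deleted_path, "w", encoding="utf-8") as fh:
            fh.write("caseid\n")
            for cid in sorted(deleted_caseids):
                fh.write(f"{cid}\n")
    pkg = QuarterlyPackage(label=label, table_paths=paths, deleted_list_path=deleted_path)
    pkg.validate()
    return pkg


def read_package(pkg: QuarterlyPackage) -> dict[str, ParseResult]:
    """Parse every table of a package; missing OUTC/THER yield empty sets."""
    pkg.validate()
    out: dict[str, ParseResult] = {}
    for name in TABLE_COLUMNS:
        path = pkg.table_paths.get(name)
        if path is not None and os.path.exists(path):
            out[name] = parse_table(path, name)
        else:
            if name in QuarterlyPackage.MANDATORY:
                raise FileNotFoundError(f"mandatory table {name} missing")
            out[name] = ParseResult(table_name=name)
    return out
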
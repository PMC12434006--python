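"""Deduplication of versioned case reports and removal of deleted cases.

A FAERS case accumulates report versions across quarters; only the most
recent version (largest FDA receipt date, then largest PRIMARYID) is
analysed. After deduplication, cases named on the quarterly deletion
lists are dropped by CASEID. Deletion lists from all quarters are
unioned before removal so a case deleted late never survives from an
early quarter.

Each stage logs an input/output count, producing the familiar
raw -> deduplicated -> post-deletion filtering funnel on any dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .records import DemoRecord

logger = logging.getLogger(__name__)

__all__ = ["CleaningReport", "deduplicate", "remove_deleted", "filter_other_tables", "clean_demo"]


@dataclass
class CleaningReport:
    """Per-stage record counts of the cleaning funnel."""

    n_raw: int
    n_after_dedup: int
    n_after_deletion: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_raw < self.n_after_dedup:
            raise ValueError("dedup cannot add records")
        if self.n_after_deletion is not None and self.n_after_deletion > self.n_after_dedup:
            raise ValueError("deletion cannot add records")


def _pid_key(primaryid: str) -> tuple[int, int, str]:
    # numeric ids compare numerically; non-numeric ties break
    # lexicographically after all numeric ids, for determinism
    if primaryid.isdigit():
        return (0, int(primaryid), "")
    return (1, 0, primaryid)


def _version_key(rec: DemoRecord) -> tuple:
    return (rec.fda_dt.sort_key(), _pid_key(rec.primaryid))


def deduplicate(demo_records: Sequence[DemoRecord]) -> tuple[list[DemoRecord], CleaningReport]:
    """Keep one report version per case: max (FDA_DT, PRIMARYID) within CASEID.

    Output is sorted by caseid, carries exactly one primaryid per
    caseid, and the operation is idempotent and order-independent.
    """
    best: dict[str, DemoRecord] = {}
    for rec in demo_records:
        cur = best.get(rec.caseid)
        if cur is None or _version_key(rec) > _version_key(cur):
            best[rec.caseid] = rec
    kept = [best[cid] for cid in sorted(best, key=_pid_key)]
    report = CleaningReport(n_raw=len(demo_records), n_after_dedup=len(kept))
    logger.info("stage=deduplicate in=%d out=%d", report.n_raw, report.n_after_dedup)
    return kept, report


def remove_deleted(
    kept_records: Sequence[DemoRecord], deleted_caseids: Iterable[str]
) -> tuple[list[DemoRecord], CleaningReport]:
    """Drop deduplicated records whose CASEID is on the deletion list."""
    deleted = set(deleted_caseids)
    surviving = [r for r in kept_records if r.caseid not in deleted]
    report = CleaningReport(
        n_raw=len(kept_records),
        n_after_dedup=len(kept_records),
        n_after_deletion=len(surviving),
    )
    logger.info("stage=remove_deleted in=%d out=%d", len(kept_records), len(surviving))
    return surviving, report


def clean_demo(
    demo_records: Sequence[DemoRecord], deleted_caseids: Iterable[str]
) -> tuple[list[DemoRecord], CleaningReport]:
    """Deduplicate then remove deleted cases, with a single funnel report."""
    kept, rep1 = deduplicate(demo_records)
    surviving, _ = remove_deleted(kept, deleted_caseids)
    return surviving, CleaningReport(
        n_raw=rep1.n_raw,
        n_after_dedup=rep1.n_after_dedup,
        n_after_deletion=len(surviving),
    )


def filter_other_tables(
    surviving_primaryids: Iterable[str], tables: dict[str, Sequence]
) -> dict[str, list]:
    """Restrict DRUG/REAC/OUTC/THER records to surviving report versions."""
    keep = set(surviving_primaryids)
    out: dict[str, list] = {}
    for name, records in tables.items():
        filtered = [r for r in records if r.primaryid in keep]
        logger.info("stage=filter_%s in=%d out=%d", name.lower(), len(records), len(filtered))
        out[name] = filtered
    return out
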
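"""PT → SOC aggregation via a user-supplied mapping table.

MedDRA itself is licensed and never bundled: the caller provides a TSV
with columns pt_name, soc_name, soc_code and is_primary_soc (pt_code
optional). A PT may be multiaxial (listed under several SOCs) but must
have exactly one primary SOC; positive signals are counted once, under
that primary SOC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PtSocMap", "load_pt_soc_map", "soc_counts", "write_pt_soc_map"]

REQUIRED = ("pt_name", "soc_name", "soc_code", "is_primary_soc")
UNMAPPED = "UNMAPPED"


def _norm_pt(name: str) -> str:
    return " ".join(str(name).split()).lower()


@dataclass
class PtSocMap:
    frame: pd.DataFrame  # normalized pt_name, soc_name, soc_code, is_primary_soc, pt_code

    def __post_init__(self) -> None:
        df = self.frame
        dup = df.duplicated(subset=["pt_name", "soc_name"])
        if dup.any():
            raise ValueError(f"duplicate (pt, soc) rows: {df.loc[dup, 'pt_name'].tolist()}")
        prim = df[df["is_primary_soc"]]
        counts = prim.groupby("pt_name").size()
        multi = counts[counts > 1]
        if not multi.empty:
            raise ValueError(f"PT(s) with more than one primary SOC: {list(multi.index)}")
        missing = set(df["pt_name"]) - set(prim["pt_name"])
        if missing:
            raise ValueError(f"PT(s) without a primary SOC: {sorted(missing)}")

    def primary_soc(self, pt: str) -> Optional[str]:
        df = self.frame
        hit = df[(df["pt_name"] == _norm_pt(pt)) & df["is_primary_soc"]]
        if hit.empty:
            return None
        return hit.iloc[0]["soc_name"]

    @property
    def primary_lookup(self) -> dict[str, str]:
        prim = self.frame[self.frame["is_primary_soc"]]
        return dict(zip(prim["pt_name"], prim["soc_name"]))


def load_pt_soc_map(path: str) -> PtSocMap:
    """Load and validate a PT→SOC TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED:
        if col not in df.columns:
            raise ValueError(f"PT-SOC map lacks column {col!r}")
    if "pt_code" not in df.columns:
        df["pt_code"] = None
    df["pt_name"] = df["pt_name"].map(_norm_pt)
    df["soc_name"] = df["soc_name"].map(lambda s: " ".join(str(s).split()))
    df["is_primary_soc"] = (
        df["is_primary_soc"].astype(str).str.strip().str.lower().isin(("1", "true", "yes", "y"))
    )
    return PtSocMap(frame=df.reset_index(drop=True))


def write_pt_soc_map(mapping: PtSocMap, path: str) -> None:
    out = mapping.frame.copy()
    out["is_primary_soc"] = out["is_primary_soc"].map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False)


def soc_counts(
    screens: Mapping[str, pd.DataFrame], mapping: PtSocMap
) -> pd.DataFrame:
    """Count positive-signal PT *types* per (group, primary SOC).

    PTs absent from the map fall into an UNMAPPED bucket with a
    warning. The sum over SOCs (including UNMAPPED) of a group's counts
    equals that group's number of positive PTs.
    """
    lookup = mapping.primary_lookup
    rows = []
    for group, df in screens.items():
        if df.empty:
            continue
        for pt in df.loc[df["positive"], "pt"]:
            soc = lookup.get(_norm_pt(pt))
            if soc is None:
                logger.warning("positive PT %r not in PT-SOC map; counted UNMAPPED", pt)
                soc = UNMAPPED
            rows.append({"group": group, "soc": soc})
    if not rows:
        return pd.DataFrame(columns=["group", "soc", "n_positive_pts"])
    out = (
        pd.DataFrame(rows)
        .groupby(["group", "soc"])
        .size()
        .rename("n_positive_pts")
        .reset_index()
        .sort_values(["group", "n_positive_pts"], ascending=[True, False], kind="stable")
        .reset_index(drop=True)
    )
    return out
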
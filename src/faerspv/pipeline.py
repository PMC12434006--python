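"""End-to-end orchestration: ingest → clean → cohort → signals → aggregate.

``run_pipeline`` executes the whole analysis on one or more quarterly
packages (real or synthetic) and writes the data-level analogues of the
study outputs: the filtering-funnel log, per-group cohort sizes, the
baseline table, country counts, onset summaries, per-group signal
tables, SOC-level positive counts and the wide IC_025 matrix, plus a
machine-readable manifest. Any stage failure aborts the run, removes
partial outputs and names the failing stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cleaning import clean_demo, filter_other_tables
from .cohort import (
    BACKGROUND_GROUPS,
    baseline_summary,
    country_counts,
    assign_cohort,
    default_synonym_table,
    load_synonym_table,
)
from .faers_io import load_deleted_cases, read_package
from .meddra import load_pt_soc_map, soc_counts
from .records import QuarterlyPackage
from .signals import ic025_matrix, screen_all_groups

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline", "compare_groups"]


@dataclass
class RunConfig:
    packages: list  # QuarterlyPackage instances
    output_dir: str
    synonyms_path: Optional[str] = None
    pt_soc_map_path: Optional[str] = None
    target_groups: Sequence[str] = BACKGROUND_GROUPS
    bcpnn_variant: str = "gamma"  # or "bate"
    onset_mode: str = "inclusive"  # or "strict"
    display_threshold_a: Optional[int] = None  # report tables keep a > threshold
    seed: int = 0

    def digest(self) -> str:
        payload = {
            "packages": [
                {"label": p.label, "tables": dict(sorted(p.table_paths.items())),
                 "deleted": p.deleted_list_path}
                for p in self.packages
            ],
            "synonyms": self.synonyms_path,
            "pt_soc_map": self.pt_soc_map_path,
            "groups": list(self.target_groups),
            "variant": self.bcpnn_variant,
            "onset_mode": self.onset_mode,
            "display_threshold_a": self.display_threshold_a,
            "seed": self.seed,
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_csv(df: pd.DataFrame, path: str, **kwargs) -> None:
    df.to_csv(path, index=kwargs.pop("index", False), **kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, returning the manifest that was written.

    Outputs land in ``config.output_dir``; on failure the directory's
    new files are removed and ``StageError`` raised.
    """
    outdir = config.output_dir
    fresh = not os.path.exists(outdir)
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []

    def _out(name: str) -> str:
        path = os.path.join(outdir, name)
        written.append(path)
        return path

    stage = "ingest"
    try:
        demo, drug, reac, outc, ther = [], [], [], [], []
        deleted: set[str] = set()
        for pkg in config.packages:
            parsed = read_package(pkg)
            demo.extend(parsed["DEMO"].records)
            drug.extend(parsed["DRUG"].records)
            reac.extend(parsed["REAC"].records)
            outc.extend(parsed["OUTC"].records)
            ther.extend(parsed["THER"].records)
            # deletion lists are unioned across quarters before removal
            deleted |= load_deleted_cases(pkg.deleted_list_path)

        stage = "clean"
        surviving, funnel = clean_demo(demo, deleted)
        pids = {r.primaryid for r in surviving}
        tables = filter_other_tables(
            pids, {"DRUG": drug, "REAC": reac, "OUTC": outc, "THER": ther}
        )
        funnel_rows = pd.DataFrame(
            [
                {"stage": "raw_reports", "n": funnel.n_raw},
                {"stage": "after_dedup", "n": funnel.n_after_dedup},
                {"stage": "after_deletion", "n": funnel.n_after_deletion},
                {"stage": "ae_records", "n": len(tables["REAC"])},
            ]
        )
        _write_csv(funnel_rows, _out("funnel.csv"))

        stage = "cohort"
        synonyms = (
            load_synonym_table(config.synonyms_path)
            if config.synonyms_path
            else default_synonym_table()
        )
        assignments = assign_cohort(surviving, tables["DRUG"], synonyms)
        sizes = (
            pd.Series([a.group for a in assignments]).value_counts().rename("n_cases")
        )
        sizes.index.name = "group"
        _write_csv(sizes.reset_index(), _out("cohort_sizes.csv"))
        background_cases = {a.caseid for a in assignments if a.is_background}

        summary = baseline_summary(
            assignments, surviving, tables["OUTC"], tables["THER"], tables["DRUG"],
            onset_mode=config.onset_mode,
        )
        _write_csv(summary.to_frame(), _out("baseline.csv"))
        for name, block in summary.quantitative.items():
            _write_csv(block, _out(f"quantitative_{name}.csv"), index=True)
        countries = country_counts(surviving, background_cases)
        _write_csv(countries.reset_index(), _out("country.csv"))

        stage = "signals"
        screens = screen_all_groups(
            tables["REAC"], assignments, surviving,
            groups=config.target_groups, variant=config.bcpnn_variant,
        )
        for g, df in screens.items():
            _write_csv(df, _out(f"signals_{g}.csv"), float_format="%.17g")
            if config.display_threshold_a is not None:
                report = df[df["a"] > config.display_threshold_a]
                _write_csv(report.round(4), _out(f"report_{g}.csv"))
        matrix = ic025_matrix(screens)
        _write_csv(matrix, _out("ic025_matrix.csv"), index=True)

        stage = "aggregate"
        if config.pt_soc_map_path:
            mapping = load_pt_soc_map(config.pt_soc_map_path)
            _write_csv(soc_counts(screens, mapping), _out("soc_counts.csv"))

        stage = "manifest"
        manifest = {
            "config_digest": config.digest(),
            "faerspv_version": __version__,
            "versions": {
                "pandas": pd.__version__,
            },
            "funnel": {row["stage"]: int(row["n"]) for _, row in funnel_rows.iterrows()},
            "groups": {g: int(sizes.get(g, 0)) for g in config.target_groups},
            "outputs": [os.path.basename(p) for p in written],
        }
        with open(_out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:  # remove partial outputs, surface the stage
        if fresh:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for path in written:
                if os.path.exists(path):
                    os.remove(path)
        raise StageError(stage, exc) from exc


def compare_groups(output_dir: str, group_a: str, group_b: str) -> pd.DataFrame:
    """Side-by-side signal table for two groups from a finished run.

    One row per PT occurring in either group; a PT absent from one
    group keeps explicit missing values on that side.
    """
    frames = {}
    for g in (group_a, group_b):
        path = os.path.join(output_dir, f"signals_{g}.csv")
        if not os.path.exists(path):
            raise FileNotFoundError(f"no signal table for group {g!r} in {output_dir}")
        df = pd.read_csv(path)
        cols = ["pt", "a", "ror", "ror_025", "ic", "ic_025", "positive"]
        if df.empty:
            df = pd.DataFrame(columns=cols)
        frames[g] = df[cols].set_index("pt").add_suffix(f"_{g}")
    merged = frames[group_a].join(frames[group_b], how="outer").reset_index()
    return merged.sort_values("pt", kind="stable").reset_index(drop=True)
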
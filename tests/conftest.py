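import os

import pandas as pd
import pytest

import faerspv
from faerspv.pipeline import RunConfig, run_pipeline


@pytest.fixture
def synonyms():
    return faerspv.default_synonym_table()


@pytest.fixture
def demo_header():
    return "primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occp_cod$reporter_country$occr_country"


def write_lines(path, lines):
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def make_demo_file(tmp_path, demo_header):
    def _make(rows, name="DEMO.txt"):
        return write_lines(tmp_path / name, [demo_header] + rows)

    return _make


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    """One full-size synthetic study: generated package, truth, pipeline outputs.

    Shared across tests; nothing mutates it. 20,000 cases with the
    default planted-signal configuration.
    """
    root = tmp_path_factory.mktemp("study")
    cfg = faerspv.default_config(seed=20240331, n_cases=20_000)
    pkg, truth = faerspv.generate(cfg, str(root / "pkg"))
    outdir = str(root / "out")
    manifest = run_pipeline(
        RunConfig(
            packages=[pkg],
            output_dir=outdir,
            pt_soc_map_path=str(root / "pkg" / "pt_soc_map.tsv"),
            display_threshold_a=100,
        )
    )
    screens = {
        g: pd.read_csv(os.path.join(outdir, f"signals_{g}.csv"))
        for g in ("IPI", "NIVO", "DURVA", "TREME", "IPI_NIVO", "DURVA_TREME")
    }
    return {
        "config": cfg,
        "package": pkg,
        "truth": truth,
        "outdir": outdir,
        "manifest": manifest,
        "screens": screens,
    }
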
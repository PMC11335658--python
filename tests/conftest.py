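from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from pvsignal.faers_io import deduplicate, load_quarter_reports, read_deleted_caseids
from pvsignal.synthetic import SynthConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

QUARTER_HEADERS = {
    "demo": "primaryid$caseid$caseversion$event_dt$age$age_cod$sex$wt$occp_cod$reporter_country$fda_dt",
    "drug": "primaryid$caseid$drug_seq$role_cod$drugname$prod_ai$route",
    "reac": "primaryid$caseid$pt",
    "outc": "primaryid$caseid$outc_cod",
    "indi": "primaryid$caseid$indi_drug_seq$indi_pt",
    "ther": "primaryid$caseid$dsg_drug_seq$start_dt",
}


def write_quarter(directory: Path, rows_by_table: dict) -> dict:
    """Write hand-crafted $-delimited quarter files for parser tests."""
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, header in QUARTER_HEADERS.items():
        rows = rows_by_table.get(name, [])
        path = directory / f"{name.upper()}TEST.txt"
        path.write_text("\n".join([header] + list(rows)) + "\n")
        paths[name] = path
    return paths


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 3,000-report synthetic quarter with planted signals, duplicates and
    deletions, shared across the suite."""
    out = tmp_path_factory.mktemp("corpus")
    config = SynthConfig(n_reports=3000, seed=11)
    paths, manifest = generate(config, out)
    return config, paths, manifest


@pytest.fixture(scope="session")
def small_reports(small_corpus):
    """The parsed, deduplicated case reports of the small corpus."""
    _, paths, manifest = small_corpus
    reports, _ = load_quarter_reports(Path(paths["demo"]).parent)
    deduped = deduplicate(reports, read_deleted_caseids(paths["deleted"]))
    return deduped, manifest
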
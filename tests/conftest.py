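from pathlib import Path

import pytest
from hypothesis import settings

from pvsignal import SimulationConfig, simulate_reports
from pvsignal.ingest import IngestReport, assemble_records
from pvsignal.constants import VORTIOXETINE_SYNONYMS
from pvsignal.synthetic import simulate_to_directory

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


SMALL_CONFIG = SimulationConfig(
    n_reports=4000,
    planted_rr={(0, 12): 8.0, (0, 0): 6.0},
    duplicate_rate=0.15,
    seed=7,
)


@pytest.fixture(scope="session")
def bundle():
    """In-memory synthetic quarterly tables plus ground truth."""
    return simulate_reports(SMALL_CONFIG)


@pytest.fixture(scope="session")
def cohort(bundle):
    tables, _ = bundle
    return assemble_records(tables, VORTIOXETINE_SYNONYMS, IngestReport())


@pytest.fixture(scope="session")
def truth(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def disk_bundle(tmp_path_factory) -> Path:
    """The same synthetic bundle written as FAERS-style ASCII files."""
    directory = tmp_path_factory.mktemp("faers_bundle")
    simulate_to_directory(SMALL_CONFIG, directory)
    return directory
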
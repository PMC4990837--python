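import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracle.py importable

from proteofilter.fixtures import FixtureSpec, write_fixture_set
from proteofilter.tabular_io import DataTable

DATA_DIR = Path(__file__).parent / "data"

# the worked-example study conditions: 200 rows, one fixed seed
WORKED_SPEC = FixtureSpec(n_rows=200, seed=42)


@pytest.fixture
def tiny_table() -> DataTable:
    """Six rows with APEX 1 = 1,3,5,7,9,11 — the hand-countable example."""
    rows = [
        [f"P{10000 + i:05d}", f"G{i}", float(2 * i + 1), 2.0, "G1"] for i in range(6)
    ]
    return DataTable(["#PROTEIN ID", "GENE", "APEX 1", "APEX 2", "TARGETS"], rows)


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """The full generated fixture family (table files, GAF, term names)."""
    directory = tmp_path_factory.mktemp("fixture_set")
    return write_fixture_set(WORKED_SPEC, directory)
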
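import pytest

from bbbscreen import CellLine, load_fixtures
from bbbscreen.mechanism import Thresholds


@pytest.fixture(scope="session")
def fixture_data():
    """(permeability summaries, in vivo records) of the packaged dataset."""
    return load_fixtures()


@pytest.fixture(scope="session")
def mdr1_summaries(fixture_data):
    summaries, _ = fixture_data
    return [s for s in summaries if s.cell_line is CellLine.MDR1]


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()
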
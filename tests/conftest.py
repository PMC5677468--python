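from pathlib import Path

import pytest

from cachescape.simulate import mirror_study_table

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def fixture_csv() -> Path:
    return DATA_DIR / "cache_fixture.csv"


@pytest.fixture(scope="session")
def mirror_records():
    """Deterministic table reproducing the reference study's stage counts."""
    return mirror_study_table(seed=0)
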
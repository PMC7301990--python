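from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from servgap import fixtures
from servgap.linguistic import TERMSET_5, TERMSET_7

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def termset_7():
    return TERMSET_7


@pytest.fixture(scope="session")
def termset_5():
    return TERMSET_5


@pytest.fixture(scope="session")
def initial_hierarchy():
    return fixtures.load_fixture("hierarchy_initial")


@pytest.fixture(scope="session")
def table3():
    return fixtures.table3_trapezoids()


@pytest.fixture(scope="session")
def table4_printed():
    """The published similarity table (24 indicators x 7 reference terms)."""
    return pd.read_csv(DATA_DIR / "table4_similarities.csv").set_index("indicator_id")


@pytest.fixture(scope="session")
def merge_plan():
    return fixtures.load_fixture("paper_merge_plan")
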
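import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from replibayes.contingency_bayes import ContingencyTable2x2
from replibayes.fixtures import reference_margins_table
from replibayes.pipeline import GROUP_LABELS


def make_table(y1: int, n1: int, y2: int, n2: int) -> ContingencyTable2x2:
    """2×2 table in (replicated, unreplicated) group order."""
    return ContingencyTable2x2(GROUP_LABELS, (y1, y2), (n1, n2))


@pytest.fixture(scope="session")
def margins_table():
    """The packaged deterministic fixture table (published margins)."""
    return reference_margins_table()


@pytest.fixture(scope="session")
def repro_table():
    """Printed replication-success table: 12 of 42 vs 22 of 54."""
    return make_table(12, 42, 22, 54)
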
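import pytest
from hypothesis import settings

from pdfsm.catalog import SignalCatalog, StateCode, load_catalog
from pdfsm.patterns import TernaryPattern
from pdfsm.table import TransitionRow, TransitionTable, load_shipped_table

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog() -> SignalCatalog:
    return load_catalog()


@pytest.fixture(scope="session")
def table() -> TransitionTable:
    """The shipped controller table under the default hold completion."""
    return load_shipped_table()


@pytest.fixture(scope="session")
def alarm_table() -> TransitionTable:
    return load_shipped_table(completion_policy="alarm")


def make_table(
    catalog: SignalCatalog,
    rows: list[tuple[str, str, str]],
    completion_policy: str = "hold",
) -> TransitionTable:
    """Build a synthetic table from (current, 16-symbol pattern, next) triples."""
    return TransitionTable(
        catalog=catalog,
        rows=[
            TransitionRow(
                current=StateCode.from_bits(cur),
                pattern=TernaryPattern.from_string(pat),
                next=StateCode.from_bits(nxt),
            )
            for cur, pat, nxt in rows
        ],
        completion_policy=completion_policy,
    )
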
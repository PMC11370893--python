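import pytest

from gut_signatures.compile import consolidate
from gut_signatures.fixtures import table1_annotations, table1_fixture


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def table1_consensus(table1):
    return consolidate(table1.records)


@pytest.fixture(scope="session")
def master_annotations():
    return table1_annotations()
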
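import pytest

from bma import builtin_schema_v1_1, load_crosswalk
from bma.fixtures import generate_documents, table1_fixture


@pytest.fixture(scope="session")
def schema():
    return builtin_schema_v1_1()


@pytest.fixture(scope="session")
def crosswalk(schema):
    return load_crosswalk(table1_fixture(), schema)


@pytest.fixture(scope="session")
def clean_docs(schema):
    return generate_documents(schema, 200, seed=7)
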
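import pytest

from readcoder import load_tables


@pytest.fixture(scope="session")
def tables():
    """Packaged lookup tables, loaded once per session."""
    return load_tables()


@pytest.fixture(scope="session")
def store(tables):
    return tables.store


@pytest.fixture(scope="session")
def lexicons(tables):
    return tables.lexicons
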
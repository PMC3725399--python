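import pytest

from cytodose import table1_fixture


@pytest.fixture(scope="session")
def fixture_table():
    """The packaged per-dose mFISH scoring counts (5 dose levels)."""
    return table1_fixture()
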
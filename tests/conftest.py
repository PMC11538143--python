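import pytest

from washtrends import SyntheticConfig, load_fixture


@pytest.fixture(scope="session")
def table2():
    """The 17 annual WASH-indicator records, 2004-2020."""
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table6():
    """The 19 global-context records, 2004-2022."""
    return load_fixture("table6")


@pytest.fixture
def default_config():
    return SyntheticConfig(seed=0)
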
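import pytest

import blcea


@pytest.fixture(scope="session")
def base_config():
    return blcea.default_config()


@pytest.fixture(scope="session")
def life_table(base_config):
    return base_config.life_table


@pytest.fixture()
def cfg(base_config):
    """A mutable copy of the base configuration."""
    return base_config.copy()
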
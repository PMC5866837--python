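import pytest

from qivive.io import default_config


@pytest.fixture(scope="session")
def config():
    """The packaged default configuration (model estrogens, rat physiology)."""
    return default_config()


@pytest.fixture(scope="session")
def e2(config):
    return config.chemicals["e2_male"]


@pytest.fixture(scope="session")
def bpa(config):
    return config.chemicals["bpa_male"]


@pytest.fixture(scope="session")
def phys(config):
    return config.physiology
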
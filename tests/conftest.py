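import pytest

from glutenprm.config import default_config


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def peptides(cfg):
    return {p.name: p for p in cfg.peptides}


@pytest.fixture(scope="session")
def sequences(peptides):
    return {name: p.sequence for name, p in peptides.items()}
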
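import pytest

import respoly


@pytest.fixture(scope="session")
def cfg():
    """Default study scenario (7 lakes x 20 crayfish per habitat)."""
    return respoly.ScenarioConfig(seed=11)


@pytest.fixture(scope="session")
def data(cfg):
    """One generated study dataset shared (read-only) across tests."""
    return respoly.generate_all(cfg)
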
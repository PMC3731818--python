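import pytest
from hypothesis import HealthCheck, settings

import hoxphys as hp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mouse():
    return hp.load_mouse_hoxd()


@pytest.fixture(scope="session")
def amphioxus():
    return hp.load_amphioxus()


@pytest.fixture(scope="session")
def modified():
    return hp.load_amphioxus_modified()


@pytest.fixture(scope="session")
def fixtures(mouse, amphioxus, modified):
    return [mouse, amphioxus, modified]
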
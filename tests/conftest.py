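import pytest
from hypothesis import HealthCheck, settings

import atakit as ak

settings.register_profile(
    "default", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def library():
    return ak.load_library()


@pytest.fixture(scope="session")
def planted_alignment():
    """Synthetic alignment with all curated fingerprints planted."""
    return ak.gen_alignment(ak.SimConfig(seed=11))


@pytest.fixture(scope="session")
def position_map(planted_alignment):
    return ak.build_position_map(planted_alignment, "TA-3N5M", ak.default_anchors())
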
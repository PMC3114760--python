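import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_region(rows, region_id="reg0", ids=None):
    from indelflank import AlignedRegionPair

    return AlignedRegionPair(region_id=region_id, rows=list(rows), ids=ids)


@pytest.fixture
def region_factory():
    return make_region
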
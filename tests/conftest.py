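import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def sphere_r5():
    from meanpath import build_fixture

    return build_fixture("sphere_homog_r5", mu_s=0.0)


@pytest.fixture
def slab_d10():
    from meanpath import build_fixture

    return build_fixture("slab_d10")


@pytest.fixture
def table2_sphere():
    from meanpath import build_fixture

    return build_fixture("table2_sphere", mu_s0=1.0)
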
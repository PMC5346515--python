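import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_subject():
    """One synthetic subject at the default study conditions, cached per test."""
    from icga.simulate import SyntheticConfig, simulate_subject

    return simulate_subject(SyntheticConfig(seed=7), 0)


@pytest.fixture
def small_tvalue_table():
    """A hand-built t-value table over 4 regions for edge-rule tests."""
    from icga.types import TValueTable

    t = np.array([[4.0, 4.0, -4.0, 1.0]])
    return TValueTable(
        betas=t.copy(),
        tvalues=t,
        residual_variance=np.ones(4),
        dof=100,
        n_volumes=102,
        n_components=1,
        component_ids=[1],
        region_ids=[1, 2, 3, 4],
    )
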
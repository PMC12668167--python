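import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from metameta import GroupSummary, effect_from_p_n
from metameta.io import meta_group_inputs

#: the three trait-level summaries printed by the source analysis
PRINTED_GROUPS = (
    ("Meta1", 6.5e-08, 1_190_454),
    ("Meta2", 1.48e-05, 568_944),
    ("Meta3", 2e-08, 14_754),
)


@pytest.fixture(scope="session")
def printed_groups():
    return [GroupSummary(label=l, p_value=p, total_n=n) for l, p, n in PRINTED_GROUPS]


@pytest.fixture(scope="session")
def pseudo_studies(printed_groups):
    """The three group summaries re-converted to Fisher-z pseudo-studies."""
    return [effect_from_p_n(g.p_value, g.total_n, g.label) for g in printed_groups]


@pytest.fixture(scope="session")
def packaged_groups_table():
    return meta_group_inputs()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
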
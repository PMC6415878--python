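import pytest
from hypothesis import HealthCheck, settings

from besurv import default_parameters

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """The bundled default parameter set (NHS England base case)."""
    return default_parameters()


@pytest.fixture(scope="session")
def base_cc(params):
    """Base-case cost-consequence result, shared across read-only tests."""
    from besurv import cost_consequence

    return cost_consequence(params)
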
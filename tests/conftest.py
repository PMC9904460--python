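import pytest
from hypothesis import HealthCheck, settings as hypothesis_settings

from mrcc_cea import full_base_case, load_config

hypothesis_settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
hypothesis_settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_config():
    """The bundled anlotinib-vs-sunitinib base-case configuration."""
    return load_config()


@pytest.fixture(scope="session")
def base_report(base_config):
    """Base-case outcomes and comparison under default conventions."""
    return full_base_case(base_config)
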
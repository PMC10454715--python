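import pytest

from acmgvus.fixtures import FIXTURE_CONFIG, builtin_cases
from acmgvus.model import ThresholdConfig


@pytest.fixture(scope="session")
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture(scope="session")
def fixture_cfg() -> ThresholdConfig:
    return FIXTURE_CONFIG


@pytest.fixture(scope="session")
def cases():
    return {case.name: case for case in builtin_cases()}
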
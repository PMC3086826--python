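from hypothesis import settings

import pytest

from steplink import ErrorModel, generate

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

SECRET = b"unit-test-secret"


@pytest.fixture(scope="session")
def secret() -> bytes:
    return SECRET


@pytest.fixture(scope="session")
def zero_error_world():
    return generate(100, ErrorModel.zero(), seed=11)


@pytest.fixture(scope="session")
def default_world():
    return generate(400, ErrorModel(), seed=12)
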
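import pytest

from acarflux.synthetic import (
    make_branched_tradeoff,
    make_linear_chain,
    make_mini_acb,
    mini_acb_media,
)


@pytest.fixture(scope="session")
def mini():
    return make_mini_acb()


@pytest.fixture(scope="session")
def media():
    return mini_acb_media()


@pytest.fixture(scope="session")
def synthesis(media):
    return media["synthesis"]


@pytest.fixture(scope="session")
def rich(media):
    return media["rich"]


@pytest.fixture
def chain():
    return make_linear_chain(2, 0.5, 10.0)


@pytest.fixture
def branched():
    return make_branched_tradeoff(10.0, 0.5, 0.3)
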
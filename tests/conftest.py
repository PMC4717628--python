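import pytest

from hymep.fixtures import (
    LINKER12_CURRENCY_IDS,
    LINKER12_HOST_COMPOUNDS,
    build_core_model,
    build_toy_db,
)
from hymep.reactions import CurrencyList


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def paper4_db():
    return build_toy_db("paper4")


@pytest.fixture(scope="session")
def linker12_db():
    return build_toy_db("linker12")


@pytest.fixture(scope="session")
def linker12_host():
    return LINKER12_HOST_COMPOUNDS


@pytest.fixture(scope="session")
def linker12_currency():
    return CurrencyList.from_ids(LINKER12_CURRENCY_IDS)


@pytest.fixture(scope="session")
def default_currency():
    return CurrencyList.default()
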
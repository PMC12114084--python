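import pytest

from tests._helpers import make_instruments, make_record, make_table


@pytest.fixture
def instrument_factory():
    return make_instruments


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def table_factory():
    return make_table
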
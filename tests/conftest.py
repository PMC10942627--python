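import pytest

from cfflux import default_constants
from cfflux.datasets import load_reference_table


@pytest.fixture(scope="session")
def constants():
    return default_constants()


@pytest.fixture(scope="session")
def reference_records():
    return load_reference_table()
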
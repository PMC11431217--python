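import pytest

from heatvalid import build_ahi_codeset


@pytest.fixture(scope="session")
def ahi():
    return build_ahi_codeset()
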
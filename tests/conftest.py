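import pytest
from hypothesis import settings

import glutencaller as gc

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lib():
    return gc.load_library()
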
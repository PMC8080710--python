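import pytest

from mhsig.simulate import random_flank_context as random_context  # noqa: F401
from mhsig.types import ScanConfig

BASES = "ACGT"


@pytest.fixture
def config():
    return ScanConfig()
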
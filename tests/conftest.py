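import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bayescreen import TestCharacteristics


@pytest.fixture
def good_test() -> TestCharacteristics:
    """A clinically plausible screening test: 90% sensitive, 80% specific."""
    return TestCharacteristics(0.9, 0.8)


@pytest.fixture
def coin_flip_test() -> TestCharacteristics:
    """Uninformative test (a + b = 1): LR+ = 1."""
    return TestCharacteristics(0.5, 0.5)


@pytest.fixture
def perverse_test() -> TestCharacteristics:
    """Test with a + b < 1: a positive result argues against disease."""
    return TestCharacteristics(0.3, 0.3)
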
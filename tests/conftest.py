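import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from pregepi.config import AlgorithmConfig


@pytest.fixture
def config() -> AlgorithmConfig:
    cfg = AlgorithmConfig()
    cfg.validate()
    return cfg
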
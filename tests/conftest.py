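import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from greytox.datasets import (
    load_acute_toxicity_panel,
    load_derivative_ptox,
    load_derivative_records,
)


@pytest.fixture(scope="session")
def panel():
    """The 14-compound x 4-receptor acute-toxicity reference panel."""
    return load_acute_toxicity_panel()


@pytest.fixture(scope="session")
def derivative_records():
    return load_derivative_records()


@pytest.fixture(scope="session")
def derivative_ptox():
    return load_derivative_ptox()
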
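import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from letdamage import load_params


@pytest.fixture(scope="session")
def db():
    return load_params()


@pytest.fixture(scope="session")
def all_params(db):
    return list(db)
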
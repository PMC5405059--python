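import sys
from pathlib import Path

import pytest

import ctbf

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable


@pytest.fixture(scope="session")
def bridges():
    """2x2 suspension/solid bridge call counts (9,9; 2,14), rows fixed."""
    return ctbf.load_example("bridges")


@pytest.fixture(scope="session")
def dolls():
    """2x2 doll-preference counts (62,27; 11,60), row sizes 89 and 71 fixed."""
    return ctbf.load_example("dolls")


@pytest.fixture(scope="session")
def siblings():
    """2x2 sibling-acceptance counts (9,6; 6,9) with all margins 15."""
    return ctbf.load_example("siblings")


@pytest.fixture(scope="session")
def occupations():
    """14x14 fathers/sons occupation counts, 775 pairs."""
    return ctbf.load_example("occupations")
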
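import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make the oracle helpers importable

from boltzmap.lattice import build_catalogue
from boltzmap.synthetic import small_lattice_suite


@pytest.fixture(scope="session")
def suite():
    """Exact catalogues and GP maps for all small test lattices."""
    return small_lattice_suite()


@pytest.fixture(scope="session")
def cat_2x3(suite):
    return suite[(2, 3)][0]


@pytest.fixture(scope="session")
def gp_2x3(suite):
    return suite[(2, 3)][1]


@pytest.fixture(scope="session")
def cat_2x4(suite):
    return suite[(2, 4)][0]


@pytest.fixture(scope="session")
def gp_2x4(suite):
    return suite[(2, 4)][1]


@pytest.fixture(scope="session")
def cat_4x4(suite):
    return suite[(4, 4)][0]


@pytest.fixture(scope="session")
def gp_4x4(suite):
    return suite[(4, 4)][1]


@pytest.fixture(scope="session")
def cat_5x5():
    """The full reversal-distinct compact 5x5 structure catalogue (L=25)."""
    return build_catalogue(5, 5)
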
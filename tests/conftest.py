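import numpy as np
import pytest

from musmb.smb import PAPER_RUN, simulate_smb
from musmb.transport import ColumnParams, SpeciesParams


@pytest.fixture(scope="session")
def column():
    return ColumnParams()


@pytest.fixture(scope="session")
def fast_column():
    """Coarser axial grid for tests where 60 cells are not needed."""
    return ColumnParams(n_cells=30)


@pytest.fixture(scope="session")
def tris():
    return SpeciesParams("tris", 121.14, pore_access=1.0, feed_conc=100.0)


@pytest.fixture(scope="session")
def mb():
    return SpeciesParams("mb", 17566.0, pore_access=0.0, feed_conc=0.2)


@pytest.fixture(scope="session")
def desalting_run(column, tris, mb):
    """Six cycles of the experimental operating point with 100 mM Tris /
    0.2 g/L Mb feed on identical columns; shared across tests."""
    return simulate_smb(PAPER_RUN, column, [tris, mb], n_cycles=6)
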
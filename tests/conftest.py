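import numpy as np
import pytest

from lptcnet import network as net
from lptcnet.cells import DEFAULT_CELL_TABLE


@pytest.fixture(scope="session")
def h1():
    return DEFAULT_CELL_TABLE["H1"]


@pytest.fixture(scope="session")
def h2():
    return DEFAULT_CELL_TABLE["H2"]


@pytest.fixture(scope="session")
def hs():
    return DEFAULT_CELL_TABLE["HS"]


@pytest.fixture(scope="session")
def topology():
    """Default connected 16-cell network (PSP-calibrated weights)."""
    return net.default_topology()


@pytest.fixture(scope="session")
def disconnected(topology):
    return net.ablate(topology, "all_lateral")


def mean_sem(values):
    v = np.asarray(values, dtype=float)
    return float(np.nanmean(v)), float(np.nanstd(v, ddof=1) / np.sqrt(len(v)))
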
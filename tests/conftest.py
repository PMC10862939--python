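import numpy as np
import pytest

from mprasim.seqlib import mutagenize
from mprasim.thermo import ThermoParams, build_architecture, consensus_promoter


@pytest.fixture(scope="session")
def promoter():
    return consensus_promoter(seed=1)


@pytest.fixture(scope="session")
def params():
    return ThermoParams()


@pytest.fixture(scope="session")
def simple_repression(promoter):
    return build_architecture("simple_repression", promoter)


@pytest.fixture(scope="session")
def small_library(promoter):
    """A 300-variant library at the standard 10% mutation rate."""
    return mutagenize(promoter, 300, 0.1, seed=11)
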
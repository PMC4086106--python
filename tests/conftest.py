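import numpy as np
import pytest

from structmap import fixtures as fx
from structmap.model import parse_pdb


@pytest.fixture
def helix():
    return fx.helix_structure(12)


@pytest.fixture
def extended():
    return fx.extended_structure(12)


@pytest.fixture
def five_res():
    return parse_pdb(fx.five_residue_pdb())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
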
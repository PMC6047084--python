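import numpy as np
import pytest

from hicforge.design import DEFAULT_SPACINGS, get_enzyme
from hicforge.simulate import make_annotated_window


@pytest.fixture
def dpnii():
    return get_enzyme("DpnII")


@pytest.fixture
def default_panel():
    return [get_enzyme(n) for n in DEFAULT_SPACINGS]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def coding_window():
    """A 40-kb annotated window (~60% CDS) shared across design tests."""
    return make_annotated_window(L=40_000, cds_fraction=0.6, seed=17)


def random_dna(n, rng):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
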
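import numpy as np
import pytest

from mimicrylab import synth


@pytest.fixture(scope="session")
def gmrca_300():
    """A 300-codon ancestral coding sequence (fixed seed)."""
    return synth.generate_gmrca(300, np.random.default_rng(12345))


@pytest.fixture(scope="session")
def gmrca_small():
    """A 40-codon ancestor for fast simulation tests."""
    return synth.generate_gmrca(40, np.random.default_rng(99))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
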
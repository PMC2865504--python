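import numpy as np
import pytest

from foldevo.study import make_study_system, make_toy_dimer


@pytest.fixture(scope="session")
def study():
    """The standard 30-residue synthetic study system (deterministic)."""
    return make_study_system()


@pytest.fixture(scope="session")
def toy_dimer():
    """2-codon, 1-contact enumerable toy: (gene, cmap, model, fitness_spec)."""
    return make_toy_dimer()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
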
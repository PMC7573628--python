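import numpy as np
import pytest

from plastburst.synthetic import angiosperm_timetree, sim_ks_mixture

PLANTED_COMPONENTS = [(0.15, 0.17, 0.05), (0.55, 1.62, 0.30), (0.30, 2.53, 0.30)]


@pytest.fixture(scope="session")
def species_tree():
    return angiosperm_timetree()


@pytest.fixture(scope="session")
def planted_mixture():
    """n=2,000 draws from the three-peak Ks mixture, with its truth."""
    x, truth = sim_ks_mixture(PLANTED_COMPONENTS, 2000, seed=7)
    return x, truth
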
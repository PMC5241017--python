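import numpy as np
import pytest

from firbiomass.synthetic import generate_trees

#: seed of the shared synthetic emulation of the 35-tree field sample
SAMPLE_SEED = 1234

#: the published sample-mean tree (D cm, H m, WD kg/m^3, V m^3) plus a
#: plausible site index for the one form that needs it
MEAN_TREE = {"D": 17.0, "H": 15.8, "WD": 304.2, "V": 0.2655, "SI": 16.0}


@pytest.fixture(scope="session")
def trees35():
    """Synthetic stand-in for the 35-tree destructive sample."""
    trees, truth = generate_trees(n_trees=35, seed=SAMPLE_SEED)
    return trees, truth


@pytest.fixture(scope="session")
def noiseless50():
    trees, truth = generate_trees(n_trees=50, seed=SAMPLE_SEED, sigma=0.0)
    return trees, truth
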
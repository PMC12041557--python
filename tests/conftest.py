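import numpy as np
import pandas as pd
import pytest

from famscan.phylo import read_newick
from famscan.preprocess import log10_traits, relative_brain_size
from famscan.synthetic import SimConfig, simulate_family_counts, \
    simulate_traits, simulate_tree


@pytest.fixture(scope="session")
def three_taxon_tree():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree46():
    return simulate_tree(46, seed=11)


@pytest.fixture(scope="session")
def traits46(tree46):
    raw = simulate_traits(tree46, seed=12)
    return relative_brain_size(log10_traits(raw))


@pytest.fixture(scope="session")
def planted_scan_data(tree46, traits46):
    """Counts with 10% of 500 families tracking log lifespan at r = 0.6."""
    cfg = SimConfig(n_families=500, frac_associated=0.10, seed=0)
    counts, truth = simulate_family_counts(
        tree46, traits46["log10_mlsp"], cfg, seed=13)
    return counts, truth


def random_tree(rng, n_tips):
    """Random coalescent-style tree used by property tests."""
    return simulate_tree(n_tips, seed=int(rng.integers(2 ** 31)))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
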
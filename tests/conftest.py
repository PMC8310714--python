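import dendropy
import numpy as np
import pandas as pd
import pytest

from sbgevo.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_species=6, n_genes=120,
                            n_individuals_per_sex=4,
                            organs=("gonad", "brain"))


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)


def tree_from_newick(nwk: str) -> dendropy.Tree:
    t = dendropy.Tree.get(data=nwk, schema="newick")
    t.is_rooted = True
    return t


@pytest.fixture()
def balanced_four_taxon_tree():
    return tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
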
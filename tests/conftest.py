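import dendropy
import pytest

from tfatlas import simulate as S


@pytest.fixture(scope="session")
def species_tree8():
    return S.simulate_species_tree(8, seed=7)


@pytest.fixture(scope="session")
def net_cfg():
    """Small network config used by several suites (fast to simulate)."""
    return S.SimConfig(seed=11, n_genes=600, n_tfs=150, n_modules=3,
                       p_in=0.15, p_out=0.01, isolated_fraction=0.33)


def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")
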
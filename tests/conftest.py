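import pytest

from cladespec import synthetic_data as sd

#: the standard 30-species fixture used by the pipeline defaults
DEFAULT_SPECIES = {
    "Gnathostomata": 6, "Ambulacraria": 2, "Lophotrochozoa": 5,
    "Nematoda": 2, "Insecta": 4, "Chelicerata": 2,
    "Cnidaria": 3, "Ctenophora": 1, "Porifera": 1, "Fungi": 4,
}


@pytest.fixture(scope="session")
def tree():
    return sd.build_species_fixture(DEFAULT_SPECIES, seed=7)


@pytest.fixture(scope="session")
def taxonomy(tree):
    return tree.to_taxonomy_table()


@pytest.fixture(scope="session")
def small_simulation(tree):
    """30 families on the default tree (no loss, for exact assertions)."""
    params = sd.FamilyParams(n_families=30, loss_prob=0.0, dup_prob=0.0,
                             subst_rate=0.05, seed=7)
    proteomes, truth = sd.simulate_gene_families(tree, params)
    return proteomes, truth


@pytest.fixture(scope="session")
def default_simulation(tree):
    """Default study conditions (loss and duplication active), 50 families."""
    params = sd.FamilyParams(n_families=50, seed=7)
    proteomes, truth = sd.simulate_gene_families(tree, params)
    return proteomes, truth
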
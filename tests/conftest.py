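import numpy as np
import pytest

from fewdrp.model import DrugResponseModel, ModelConfig
from fewdrp.pathway_network import (GeneNetwork, OmicsProfile,
                                    PathwayCollection, build_subnetwork)
from fewdrp.synthetic import FixtureConfig, make_fixture


@pytest.fixture(scope="session")
def tiny_collection():
    """Six disjoint 10-gene pathways over 60 genes."""
    genes = [f"g{i:03d}" for i in range(60)]
    return PathwayCollection(
        [(f"pw{p}", frozenset(genes[10 * p:10 * p + 10])) for p in range(6)])


@pytest.fixture(scope="session")
def tiny_network(tiny_collection):
    rng = np.random.default_rng(0)
    genes = sorted(tiny_collection.gene_universe)
    edges = [(genes[i], genes[j])
             for i in range(len(genes))
             for j in rng.choice(len(genes), 3) if i != j]
    return build_subnetwork(edges, tiny_collection)


@pytest.fixture(scope="session")
def tiny_model(tiny_network, tiny_collection):
    cfg = ModelConfig.desk()
    cfg.dropout = 0.0
    cfg.drug.dropout = 0.0
    return DrugResponseModel(tiny_network, tiny_collection, cfg, n_omics=4)


@pytest.fixture(scope="session")
def tiny_params(tiny_model):
    return tiny_model.init_params(0)


@pytest.fixture(scope="session")
def small_fixture():
    """Reduced synthetic screen shared by the slower unit tests."""
    return make_fixture(FixtureConfig(n_genes=80, n_pathways=8,
                                      pathway_size=(5, 8), n_drugs=8,
                                      n_target_classes=3, n_tissues=2,
                                      samples_per_tissue=32, seed=3))


@pytest.fixture
def path_profile():
    """3-gene path a-b-c with one missing value on the middle node."""
    net = GeneNetwork(gene_ids=["a", "b", "c"],
                      edges={frozenset(("a", "b")), frozenset(("b", "c"))},
                      adjacency=np.array([[0., 1., 0.],
                                          [1., 0., 1.],
                                          [0., 1., 0.]]))
    values = np.array([[1.0], [0.0], [3.0]])
    observed = np.array([[True], [False], [True]])
    prof = OmicsProfile(sample_id="s", tissue="t", values=values,
                        observed=observed)
    return net, prof
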
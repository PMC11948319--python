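import numpy as np
import pytest

from tautrank.chem import Conformer3D, parse_structure
from tautrank.nn.model import ModelConfig, build_graph, init_params
from tautrank.tautomers import load_rules


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def small_model_config():
    return ModelConfig(
        embedding_dim=16, n_interaction=2, n_residual=1, n_output_residual=1, n_rbf=8
    )


@pytest.fixture()
def small_params(small_model_config):
    rng = np.random.default_rng(7)
    params = init_params(small_model_config, seed=7)
    # non-trivial output head so predictions are not identically zero
    params["out.W"].data[:] = rng.normal(scale=0.1, size=params["out.W"].shape)
    params["out.b"].data[:] = rng.normal(scale=0.1, size=params["out.b"].shape)
    return params


@pytest.fixture()
def random_graph_factory(small_model_config):
    def factory(n_atoms=5, seed=0, spread=2.5):
        rng = np.random.default_rng(seed)
        coords = rng.normal(scale=spread, size=(n_atoms, 3))
        z = rng.choice([1, 6, 7, 8], size=n_atoms)
        return build_graph(
            Conformer3D(coords), atomic_numbers=z, cutoff=small_model_config.cutoff
        ), coords, z

    return factory


@pytest.fixture(scope="session")
def acetone():
    return parse_structure("CC(C)=O")


@pytest.fixture(scope="session")
def pyridone():
    return parse_structure("O=c1cccc[nH]1")
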
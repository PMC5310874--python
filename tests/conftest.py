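import numpy as np
import pytest

from gapc.data_model import StudyDimensions
from gapc.inference import fit_gapc
from gapc.simulate import SimulationConfig, lattice_graph, simulate_gapc_dataset
from gapc.structure import ModelSpec


@pytest.fixture(scope="session")
def tiny_setup():
    """Small grid (G=2, A=4, I=4, T=5, type-I interaction) with one simulated dataset."""
    dims = StudyDimensions(G=2, A=4, I=4, T=5)
    graph = lattice_graph(2, 2)
    spec = ModelSpec(dims=dims, interaction_type="I")
    dataset, truth = simulate_gapc_dataset(spec, graph, SimulationConfig(), seed=7)
    return spec, graph, dataset, truth


@pytest.fixture(scope="session")
def tiny_fit(tiny_setup):
    """One modest MCMC fit of the tiny dataset, shared across test modules."""
    spec, graph, dataset, truth = tiny_setup
    result = fit_gapc(dataset, graph, spec, chains=2, iterations=400, seed=11)
    return spec, graph, dataset, truth, result


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
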
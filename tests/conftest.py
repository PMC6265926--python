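import numpy as np
import pandas as pd
import pytest

from geologit.dataset import CLUSTER, DISTRICT, OUTCOME, SurveyDataset
from geologit.inference import MCMCSettings, ModelSpec, fit_model
from geologit.simulate import make_lattice_adjacency, simulate_survey
from geologit.studies import recovery_mcmc, recovery_model_spec, recovery_sim_spec


@pytest.fixture(scope="session")
def lattice():
    return make_lattice_adjacency(5, 6)


@pytest.fixture(scope="session")
def path3():
    """Three regions in a path: 1-2, 2-3."""
    from geologit.graph import AdjacencyGraph

    return AdjacencyGraph(
        region_ids=[1, 2, 3], neighbors={1: {2}, 2: {1, 3}, 3: {2}}
    )


@pytest.fixture(scope="session")
def recovery_dataset():
    """One synthetic survey at the standard recovery conditions."""
    return simulate_survey(recovery_sim_spec(seed=7313))


@pytest.fixture(scope="session")
def small_fit(recovery_dataset):
    """A quick Model 4 fit reused by summary/DIC/constraint tests."""
    spec = recovery_model_spec(4)
    mcmc = MCMCSettings(iterations=400, burn_in=100, thinning=2, seed=99)
    graph = make_lattice_adjacency(5, 6)
    draws = fit_model(recovery_dataset, graph, spec, mcmc)
    return draws, recovery_dataset, graph


@pytest.fixture()
def intercept_only_data():
    """35 users among 100 records: the quadrature-oracle case."""
    y = np.array([1] * 35 + [0] * 65)
    df = pd.DataFrame({OUTCOME: y, DISTRICT: 1, CLUSTER: 1})
    return SurveyDataset(df)


def intercept_only_spec():
    return ModelSpec(model_id=1, fixed_references={}, linear_covariates=[])
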
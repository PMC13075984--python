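import numpy as np
import pytest

import scgeno as sg


@pytest.fixture(scope="session")
def sim_config():
    """Default study conditions, small enough for fast tests."""
    return sg.SimulationConfig(seed=20)


@pytest.fixture(scope="session")
def sim_data(sim_config):
    """Simulated experiment: (pairs, truth, annotation)."""
    return sg.simulate_experiment(sim_config)


@pytest.fixture(scope="session")
def sim_chains(sim_data):
    pairs, _, annot = sim_data
    chains = []
    for pair in pairs:
        chains.extend(sg.chains_from_counts(pair, annot))
    return chains


@pytest.fixture(scope="session")
def fitted(sim_chains):
    """Model fitted once on the simulated chains (shared across tests)."""
    return sg.GenotypeHMM(sim_chains).fit(seed=20)


@pytest.fixture()
def well_separated_params():
    """Ground-truth-style parameters with clearly distinct emission rows."""
    return sg.HMMParams(
        pi=[0.5, 0.5],
        A=[[0.998, 0.002], [0.002, 0.998]],
        B=[
            [0.01, 0.01, 0.03, 0.10, 0.25, 0.60],
            [0.55, 0.35, 0.06, 0.02, 0.01, 0.01],
        ],
    )


def make_chain(states, replicate="r1", chrom="chr1", starts=None):
    states = np.asarray(states, dtype=np.int64)
    return sg.ObservedChain(
        replicate_id=replicate,
        chromosome=chrom,
        gene_ids=np.array([f"{chrom}_g{i}" for i in range(len(states))], dtype=object),
        states=states,
        starts=starts,
    )
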
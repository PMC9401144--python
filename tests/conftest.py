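import numpy as np
import pytest

import carenet as cn


@pytest.fixture(scope="session")
def small_world():
    """One seeded desk-scale simulation shared across tests."""
    cfg = cn.SynthConfig(n_patients=400, n_providers=90, seed=7)
    providers, patients, claims, truth = cn.simulate(cfg)
    return {"config": cfg, "providers": providers, "patients": patients,
            "claims": claims, "truth": truth}


@pytest.fixture(scope="session")
def small_network(small_world):
    bip = cn.build_bipartite(small_world["claims"])
    G = cn.giant_component(cn.project_cosine(bip, small_world["providers"]))
    return G


@pytest.fixture(scope="session")
def small_cases(small_world, small_network):
    eps = cn.link_records(small_world["claims"])
    return cn.filter_cases(eps, set(small_network.nodes))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
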
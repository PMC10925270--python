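import numpy as np
import pytest

import gsnn


@pytest.fixture(scope="session")
def smoke_spec():
    return gsnn.FixtureSpec()


@pytest.fixture(scope="session")
def smoke_tables(smoke_spec):
    return gsnn.generate_interaction_tables(smoke_spec)


@pytest.fixture(scope="session")
def smoke_graph(smoke_spec):
    return gsnn.generate_graph(smoke_spec)


@pytest.fixture(scope="session")
def smoke_sim(smoke_spec, smoke_graph):
    return gsnn.simulate_responses(smoke_graph, smoke_spec)


@pytest.fixture(scope="session")
def smoke_dataset(smoke_sim, smoke_graph):
    obs = smoke_sim.observations()
    X, Y = gsnn.encode_dataset(obs, smoke_graph)
    return obs, X, Y


@pytest.fixture(scope="session")
def chain_graph():
    """Smallest legal graph: drug -> protein -> readout."""
    return gsnn.StructuralGraph.from_lists(
        [("drugA", "DRUG"), ("protP", "PROTEIN"), ("lincsG", "LINCS")],
        [("drugA", "protP"), ("protP", "lincsG")])


@pytest.fixture(scope="session")
def planted_instance():
    """Planted-path fixture with a model trained on it (seed 0)."""
    g, sim, planted = gsnn.planted_path_instance(seed=0, path_len=3)
    obs = sim.observations()
    X, Y = gsnn.encode_dataset(obs, g)
    model = gsnn.GSNN(g, gsnn.GsnnConfig(channels=4, layers=5, seed=0))
    model.fit(X, Y, epochs=200, lr=1e-2, batch_size=8)
    return g, sim, planted, model


def pick_explain_pair(g, sim, dose=2.0):
    """Dosed observation with the largest ground-truth effect + its baseline."""
    obs = sim.observations()
    drug = next(o.meta["drugs"][0] for o in obs if o.meta["drugs"])
    effects = {c: np.abs(sim.noiseless_response(c, {drug: dose})
                         - sim.noiseless_response(c)).max()
               for c in sim.cell_lines}
    cell = max(effects, key=effects.get)
    dosed = next(o for o in obs if o.meta["drugs"]
                 and o.meta["dose"] == dose and o.meta["cell_line"] == cell)
    baseline = next(o for o in obs if not o.meta["drugs"]
                    and o.meta["cell_line"] == cell)
    return (gsnn.encode_observation(dosed, g),
            gsnn.encode_observation(baseline, g))
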
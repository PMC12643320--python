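import numpy as np
import pandas as pd
import pytest

from srtrace import graphs, rt_model, synth


@pytest.fixture(scope="session")
def modular():
    return graphs.make_modular_graph()

@pytest.fixture(scope="session")
def lattice():
    return graphs.make_lattice_graph()

@pytest.fixture(scope="session")
def random_graph():
    return graphs.make_random_graph(seed=1)

@pytest.fixture(scope="session")
def all_graphs(modular, lattice, random_graph):
    return {"modular": modular, "lattice": lattice, "random": random_graph}


@pytest.fixture(scope="session")
def two_cycle():
    """Deterministic 2-state alternation: the smallest SR testbed."""
    return graphs.Graph(np.array([[0, 1], [1, 0]], dtype=np.int8))


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject, 700-trial combined-model cohort shared by plumbing tests."""
    spec = synth.CohortSpec(n_subjects=6, stages_per_subject=1, n_trials=700, seed=42)
    df, truth = synth.simulate_cohort(spec)
    return rt_model.preprocess(df), truth


def make_agent_table(model, n_agents, n_trials, seed0, graph_family="modular",
                     graph=None, **param_overrides):
    """Simulate a homogeneous group of agents as one preprocessed trial table."""
    tables = []
    for i in range(n_agents):
        g = graph if graph is not None else graphs.make_graph(graph_family, seed=seed0 + 7 * i)
        params = dict(mu0=6.0, beta_trial=0.0, beta_A=-2.0, beta_W=-1.0,
                      beta_ntrials=0.0, beta_lag10=0.0, alpha_A=0.15,
                      alpha_W=0.15, gamma=0.8, lam=0.7, sigma=0.15)
        params.update(param_overrides)
        agent = synth.AgentSpec(model=model, params=params, shift_ms=250.0,
                                error_rate=0.0, fastguess_rate=0.0)
        tables.append(
            synth.simulate_subject(agent, g, n_trials, stage=1, seed=seed0 + i,
                                   subject=f"a{i:03d}", graphset=f"{graph_family}-1")
        )
    return rt_model.preprocess(pd.concat(tables, ignore_index=True))
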
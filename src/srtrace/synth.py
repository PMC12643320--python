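"""Synthetic graph-walk SRT cohorts with known generative parameters.

Generates behavioral tables with the exact statistical structure the fitting
pipeline assumes: random walks on 15-node graphs, reaction times sampled from
the shifted log-normal observation model driven by a chosen learner, a seeded
random node-to-motor-target bijection per subject, and configurable rates of
incorrect trials and implausibly fast (< 30 ms) guesses.  Every dataset comes
with a truth record for parameter- and model-recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import graphs as graphs_mod
from .graphs import Graph, random_walk, N_NODES
from .hierarchical import to_natural, to_unconstrained, vector_to_natural
from .rt_model import MODELS, ModelSpec, Session, mu_series, nuisance_regressors

DEFAULT_N_TRIALS = 1500

# Generative group-level defaults (natural scale).  Reaction times center
# around ~650 ms with a ~250 ms irreducible motor shift; expectancy weights
# are negative (higher expectancy -> faster responses); discount and trace
# parameters sit in the range estimated for human learners.
DEFAULT_GROUP_NATURAL = {
    "mu0": 6.0,
    "beta_trial": -0.15,
    "beta_A": -2.0,
    "beta_W": -1.0,
    "beta_ntrials": 0.02,
    "beta_lag10": -0.02,
    "alpha_A": 0.15,
    "alpha_W": 0.15,
    "gamma": 0.80,
    "lam": 0.70,
    "sigma": 0.20,
}

# Between-subject SDs on the unconstrained scale (logit/log/identity).
DEFAULT_GROUP_SD = {
    "mu0": 0.15,
    "beta_trial": 0.10,
    "beta_A": 0.5,
    "beta_W": 0.5,
    "beta_ntrials": 0.02,
    "beta_lag10": 0.02,
    "alpha_A": 0.6,
    "alpha_W": 0.6,
    "gamma": 0.6,
    "lam": 0.8,
    "sigma": 0.15,
}

TARGET_OFFSET_SD = 0.05  # per-subject motor-category offsets, log-RT units


@dataclass
class AgentSpec:
    """One simulated learner: model identity, parameters, contamination rates."""

    model: str = "combined_sr_td"
    params: dict[str, float] = field(default_factory=dict)
    shift_ms: float = 250.0
    error_rate: float = 0.03
    fastguess_rate: float = 0.005

    def model_spec(self) -> ModelSpec:
        return MODELS[self.model]


@dataclass
class CohortSpec:
    """A cohort of simulated subjects sharing a graph family and group distribution."""

    n_subjects: int = 40
    graph_family: str = "modular"
    stages_per_subject: int = 2
    n_trials: int = DEFAULT_N_TRIALS
    model: str = "combined_sr_td"
    group_natural: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_NATURAL))
    group_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_SD))
    stage_coef: dict[str, float] = field(default_factory=dict)  # unconstrained scale
    shift_ms_mean: float = 250.0
    shift_ms_sd: float = 25.0
    target_offset_sd: float = TARGET_OFFSET_SD
    error_rate: float = 0.03
    fastguess_rate: float = 0.005
    seed: int = 0


def _relevant_params(model: ModelSpec) -> list[str]:
    names = ["mu0", "beta_trial", "sigma"]
    if model.a_kind is not None:
        names += ["beta_A", "beta_ntrials", "beta_lag10"]
    if model.has_recency:
        names.append("beta_W")
    names += list(model.learner_params)
    return names


def simulate_subject(
    agent: AgentSpec,
    graph: Graph,
    n_trials: int,
    stage: int,
    seed: int,
    subject: str = "s001",
    graphset: str = "g1",
) -> pd.DataFrame:
    """Simulate one subject x stage session as a trial table.

    Walks the graph, advances the agent's learner(s), assembles mu_t exactly
    as the matching fit model does, samples rt = shift + exp(N(mu_t, sigma^2)),
    then injects incorrect trials (flagged, RT kept) and fast guesses
    (rt ~ U(1, 30) ms, flagged correct) at the configured rates.
    """
    rng = np.random.default_rng(seed)
    walk = random_walk(graph, n_trials, seed=int(rng.integers(2**31)), stage=stage)
    # seeded random bijection of nodes to motor-target categories
    target_of_node = rng.permutation(graph.n_nodes)
    targets = target_of_node[walk.nodes]
    model = agent.model_spec()
    params = dict(agent.params)
    # session scaffold: trial/nuisance regressors identical to the fit side
    session = Session(
        subject=subject, graphset=graphset, stage=stage,
        stage_covariate=-1.0 if stage == 1 else 1.0,
        nodes=walk.nodes, targets=targets,
        rt_ms=np.full(n_trials, 1000.0), include=np.ones(n_trials, dtype=bool),
        trial_scaled=np.linspace(0.0, 1.0, n_trials),
        n_nodes=graph.n_nodes, n_equil=0,  # generation has no equilibration cut
    )
    mu = mu_series(model, session, params)
    rt = agent.shift_ms + np.exp(rng.normal(mu, params["sigma"]))
    correct = np.ones(n_trials, dtype=bool)
    err = rng.random(n_trials) < agent.error_rate
    correct[err] = False
    fast = rng.random(n_trials) < agent.fastguess_rate
    rt[fast] = rng.uniform(1.0, 30.0, size=int(fast.sum()))
    return pd.DataFrame(
        {
            "subject": subject,
            "graphset": graphset,
            "stage": stage,
            "trial": np.arange(1, n_trials + 1),
            "node": walk.nodes + 1,
            "target": targets + 1,
            "rt_ms": np.round(rt, 4),
            "correct": correct,
        }
    )


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort; returns (trial table, truth record).

    Session-level parameters are drawn on the unconstrained scale from
    N(group_mean + c * stage_coef, diag(sd^2)) with stage covariate
    c = -1 (first stage) or +1 (second); for single-stage subjects the stage
    assignment is counterbalanced across subjects.
    """
    rng = np.random.default_rng(spec.seed)
    model = MODELS[spec.model]
    pnames = _relevant_params(model)
    mean_u = {p: to_unconstrained(p, spec.group_natural[p]) for p in pnames}
    tables = []
    truth_sessions = []
    for i in range(spec.n_subjects):
        subject = f"s{i + 1:03d}"
        if spec.stages_per_subject == 2:
            stage_list = [1, 2]
        else:
            stage_list = [1 if i % 2 == 0 else 2]
        gseed = int(rng.integers(2**31))
        shift_ms = float(max(50.0, rng.normal(spec.shift_ms_mean, spec.shift_ms_sd)))
        toff = rng.normal(0.0, spec.target_offset_sd, size=N_NODES - 1)
        for stage in stage_list:
            c = -1.0 if stage == 1 else 1.0
            params_u = {
                p: mean_u[p] + c * spec.stage_coef.get(p, 0.0)
                + spec.group_sd.get(p, 0.0) * rng.standard_normal()
                for p in pnames
            }
            params = {p: to_natural(p, v) for p, v in params_u.items()}
            for k in range(2, N_NODES + 1):
                params[f"target_{k}"] = float(toff[k - 2])
            graph = graphs_mod.make_graph(spec.graph_family, seed=gseed + stage)
            graphset = f"{spec.graph_family}-{stage}"
            agent = AgentSpec(model=spec.model, params=params, shift_ms=shift_ms,
                              error_rate=spec.error_rate,
                              fastguess_rate=spec.fastguess_rate)
            tables.append(
                simulate_subject(agent, graph, spec.n_trials, stage,
                                 seed=int(rng.integers(2**31)),
                                 subject=subject, graphset=graphset)
            )
            truth_sessions.append(
                {
                    "subject": subject, "graphset": graphset, "stage": stage,
                    "covariate": c,
                    "params_natural": {k: float(v) for k, v in params.items()},
                    "params_unconstrained": {k: float(v) for k, v in params_u.items()},
                    "shift_ms": shift_ms,
                }
            )
    truth = {
        "model": spec.model,
        "group_natural": {p: spec.group_natural[p] for p in pnames},
        "group_unconstrained": mean_u,
        "group_sd_unconstrained": {p: spec.group_sd.get(p, 0.0) for p in pnames},
        "stage_coef_unconstrained": dict(spec.stage_coef),
        "sessions": truth_sessions,
        "seed": spec.seed,
    }
    return pd.concat(tables, ignore_index=True), truth


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def recovery_report(truth: dict, fits, parameters: list[str] | None = None) -> pd.DataFrame:
    """Per-parameter truth-vs-estimate recovery statistics on the unconstrained scale.

    ``fits`` is an EMResult or a list of SubjectFit; sessions are matched to
    the truth record by (subject, graphset, stage).  Reports subject-level
    Pearson r, bias, and RMSE per parameter.
    """
    fit_list = getattr(fits, "fits", fits)
    by_key = {(f.subject, f.graphset, f.stage): f for f in fit_list}
    rows = []
    matched = []
    for ts in truth["sessions"]:
        key = (ts["subject"], ts["graphset"], ts["stage"])
        if key not in by_key:
            raise ValueError(f"no fit for session {key}")
        matched.append((ts, by_key[key]))
    if parameters is None:
        parameters = [p for p in truth["group_unconstrained"]
                      if p in matched[0][1].names]
    for p in parameters:
        t = np.array([to_unconstrained(p, ts["params_natural"][p]) for ts, _ in matched])
        e = np.array([f.theta_map[f.names.index(p)] for _, f in matched])
        r = float(np.corrcoef(t, e)[0, 1]) if t.std() > 0 and e.std() > 0 else np.nan
        rows.append(
            {
                "parameter": p,
                "pearson_r": r,
                "bias": float((e - t).mean()),
                "rmse": float(np.sqrt(((e - t) ** 2).mean())),
                "truth_group_mean": float(t.mean()),
                "est_group_mean": float(e.mean()),
                "n": len(t),
            }
        )
    return pd.DataFrame(rows)
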
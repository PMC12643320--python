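"""Shifted log-normal reaction-time model driven by trial-by-trial learner predictions.

A trial's reaction time is modeled as log(rt - shift) ~ N(mu_t, sigma^2),
where the shift is a fitted fraction of the subject's minimum observed RT and
mu_t is a linear predictor assembled from a baseline, a practice slope on the
rescaled trial number, motor-target offsets, the learner expectancy of the
upcoming node, and two recency nuisance regressors (trials since the node
last occurred, and log count of the node in the preceding 10 trials).

Incorrect trials and implausibly fast trials (rt < 30 ms) never contribute
likelihood but always advance the learner state, and the first 500 trials of
each 1500-trial stage equilibrate the learner without contributing
likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .graphs import N_NODES
from .learners import analytic_sr, static_sr
from .graphs import empirical_transition_matrix

log = logging.getLogger(__name__)

MIN_PLAUSIBLE_RT_MS = 30.0
N_EQUILIBRATION = 500

TRIAL_COLUMNS = ["subject", "graphset", "stage", "trial", "node", "target", "rt_ms", "correct"]


# --------------------------------------------------------------------------
# model menu

@dataclass(frozen=True)
class ModelSpec:
    """Which predictor(s) a model uses and which learner parameters it owns.

    ``a_kind`` names the higher-order (or sole) expectancy component;
    ``has_recency`` adds the unconditional recency expectancy W alongside it
    (the combined models).  ``fixed`` pins learner parameters at constants
    (used e.g. to fix lambda = 1).
    """

    name: str
    a_kind: str | None  # None | recency | onestep | sr_td | sr_static | hebbian
    has_recency: bool = False
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def learner_params(self) -> tuple[str, ...]:
        out: list[str] = []
        if self.a_kind in ("recency", "onestep"):
            out.append("alpha_A")
        elif self.a_kind == "sr_td":
            out += ["alpha_A", "gamma", "lam"]
        elif self.a_kind == "sr_static":
            out.append("gamma")
        elif self.a_kind == "hebbian":
            out += ["alpha_A", "gamma"]
        if self.has_recency:
            out.append("alpha_W")
        return tuple(p for p in out if p not in self.fixed)


MODELS: dict[str, ModelSpec] = {
    "baseline": ModelSpec("baseline", None),
    "recency": ModelSpec("recency", "recency"),
    "onestep": ModelSpec("onestep", "onestep"),
    "sr_td": ModelSpec("sr_td", "sr_td"),
    "sr_static": ModelSpec("sr_static", "sr_static"),
    "combined_onestep": ModelSpec("combined_onestep", "onestep", has_recency=True),
    "combined_sr_td": ModelSpec("combined_sr_td", "sr_td", has_recency=True),
    "combined_sr_static": ModelSpec("combined_sr_static", "sr_static", has_recency=True),
    "combined_sr_td_lam1": ModelSpec(
        "combined_sr_td_lam1", "sr_td", has_recency=True, fixed={"lam": 1.0}
    ),
    # trace-only Hebbian learner: the bootstrap-free lambda=1 reference used
    # for signature simulations, not for subject fitting
    "hebbian_trace": ModelSpec("hebbian_trace", "hebbian"),
}


def param_names(model: ModelSpec, include_targets: bool = True, include_nuisance: bool = True) -> list[str]:
    """Ordered parameter names: linear block first, then nonlinear block.

    The baseline model carries no expectancy or nuisance terms at all (it is
    the no-prediction reference).
    """
    names = ["mu0", "beta_trial"]
    if include_targets:
        names += [f"target_{k}" for k in range(2, N_NODES + 1)]
    if model.a_kind is not None:
        names.append("beta_A")
    if model.has_recency:
        names.append("beta_W")
    if model.a_kind is not None and include_nuisance:
        names += ["beta_ntrials", "beta_lag10"]
    names += list(model.learner_params)
    names += ["shift_frac", "sigma"]
    return names


def linear_param_names(model: ModelSpec, include_targets: bool = True, include_nuisance: bool = True) -> list[str]:
    nonlin = set(model.learner_params) | {"shift_frac", "sigma"}
    return [p for p in param_names(model, include_targets, include_nuisance) if p not in nonlin]


# --------------------------------------------------------------------------
# preprocessing

def preprocess(raw: pd.DataFrame) -> pd.DataFrame:
    """Validate and annotate a trial table.

    Adds ``include`` (correct and rt >= 30 ms: contributes likelihood) and
    ``trial_scaled`` (trial rescaled to [0, 1] within subject x graphset x
    stage).  Excluded rows are retained: the learner state sees the full node
    sequence.
    """
    if len(raw) == 0:
        raise ValueError("empty trial table")
    df = raw.copy()
    df["correct"] = df["correct"].astype(bool)
    df["include"] = df["correct"] & (df["rt_ms"] >= MIN_PLAUSIBLE_RT_MS)
    keys = ["subject", "graphset", "stage"]
    df = df.sort_values(keys + ["trial"], kind="stable").reset_index(drop=True)

    def _scale(t: pd.Series) -> pd.Series:
        n = len(t)
        if n == 1:
            return pd.Series([1.0], index=t.index)
        return (t - t.min()) / (t.max() - t.min())

    df["trial_scaled"] = df.groupby(keys, sort=False)["trial"].transform(_scale)
    n_excl = int((~df["include"]).sum())
    if n_excl:
        log.info("preprocess: %d of %d trials excluded from likelihood", n_excl, len(df))
    return df


def nuisance_regressors(nodes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Recency nuisance series for a node sequence.

    r_ntrials[t]: trials since node_t last occurred (the trial index itself,
    and flagged via log, for a first occurrence).  r_lag10[t]: log(1 + count
    of node_t within trials t-10..t-1); the +1 keeps a zero count finite.
    """
    nodes = np.asarray(nodes, dtype=np.int64)
    T = len(nodes)
    last_seen = {}
    r_ntrials = np.empty(T)
    r_lag10 = np.empty(T)
    for t in range(T):
        s = int(nodes[t])
        r_ntrials[t] = t - last_seen[s] if s in last_seen else max(t, 1)
        lo = max(0, t - 10)
        r_lag10[t] = np.log1p(int(np.sum(nodes[lo:t] == s)))
        last_seen[s] = t
    return r_ntrials, r_lag10


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


@dataclass
class Session:
    """One subject x stage sequence prepared for likelihood evaluation."""

    subject: str
    graphset: str
    stage: int
    stage_covariate: float  # -1 first stage, +1 second stage
    nodes: np.ndarray
    targets: np.ndarray  # motor categories, 0-based
    rt_ms: np.ndarray
    include: np.ndarray  # bool: valid-RT trials
    trial_scaled: np.ndarray
    n_nodes: int = N_NODES
    n_equil: int = N_EQUILIBRATION
    z_nuisance: bool = True
    r_ntrials: np.ndarray = field(init=False)
    r_lag10: np.ndarray = field(init=False)
    lik_mask: np.ndarray = field(init=False)
    min_rt: float = field(init=False)

    def __post_init__(self) -> None:
        rn, rl = nuisance_regressors(self.nodes)
        if self.z_nuisance:
            rn, rl = _zscore(rn), _zscore(rl)
        self.r_ntrials, self.r_lag10 = rn, rl
        t_index = np.arange(len(self.nodes))
        if len(self.nodes) <= self.n_equil:
            raise ValueError(
                f"session has {len(self.nodes)} trials, fewer than the "
                f"{self.n_equil}-trial equilibration window"
            )
        self.lik_mask = self.include & (t_index >= self.n_equil)
        if not self.lik_mask.any():
            raise ValueError("no trials contribute likelihood")
        self.min_rt = float(self.rt_ms[self.include].min())


def sessions_from_table(
    df: pd.DataFrame, n_nodes: int = N_NODES, n_equil: int = N_EQUILIBRATION,
    z_nuisance: bool = True,
) -> list[Session]:
    """Split a preprocessed trial table into per-(subject, graphset, stage) sessions."""
    if "include" not in df.columns:
        df = preprocess(df)
    out = []
    for (subj, gs, stage), g in df.groupby(["subject", "graphset", "stage"], sort=True):
        out.append(
            Session(
                subject=str(subj),
                graphset=str(gs),
                stage=int(stage),
                stage_covariate=-1.0 if int(stage) == 1 else 1.0,
                nodes=g["node"].to_numpy(dtype=np.int64) - 1,
                targets=g["target"].to_numpy(dtype=np.int64) - 1,
                rt_ms=g["rt_ms"].to_numpy(dtype=float),
                include=g["include"].to_numpy(dtype=bool),
                trial_scaled=g["trial_scaled"].to_numpy(dtype=float),
                n_nodes=n_nodes,
                n_equil=n_equil,
                z_nuisance=z_nuisance,
            )
        )
    return out


# --------------------------------------------------------------------------
# predictor series

def predictor_series(
    kind: str, nodes: np.ndarray, n: int, params: dict[str, float]
) -> np.ndarray:
    """Per-trial expectancy of the upcoming node under one learner.

    Values are read from the learner state before it observes the trial.
    Raises FloatingPointError on SR divergence (the fit path converts this to
    an infinite NLL).
    """
    nodes = np.ascontiguousarray(nodes, dtype=np.int64)
    if kind == "recency":
        return _kernels.recency_series(nodes, n, params["alpha_A"])
    if kind == "onestep":
        return _kernels.onestep_series(nodes, n, params["alpha_A"])
    if kind == "sr_td":
        out, ok = _kernels.srtd_series(nodes, n, params["alpha_A"], params["gamma"], params["lam"])
        if not ok:
            raise FloatingPointError("SR-TD diverged")
        return out
    if kind == "hebbian":
        return _kernels.hebbian_series(nodes, n, params["alpha_A"], params["gamma"])
    if kind == "sr_static":
        t_hat = empirical_transition_matrix(nodes, n)
        m = analytic_sr(t_hat, params["gamma"])
        row_sums = m.sum(axis=1)
        out = np.empty(len(nodes))
        out[0] = 1.0 / n
        sp, st = nodes[:-1], nodes[1:]
        out[1:] = m[sp, st] / row_sums[sp]
        return out
    raise ValueError(f"unknown predictor kind: {kind!r}")


def mu_series(model: ModelSpec, session: Session, params: dict[str, float],
              include_targets: bool = True, include_nuisance: bool = True) -> np.ndarray:
    """Assemble the per-trial linear predictor mu_t for one session."""
    mu = np.full(len(session.nodes), params["mu0"], dtype=float)
    mu += params["beta_trial"] * session.trial_scaled
    if include_targets:
        offsets = np.zeros(session.n_nodes)
        for k in range(2, session.n_nodes + 1):
            offsets[k - 1] = params.get(f"target_{k}", 0.0)
        mu += offsets[session.targets]
    if model.a_kind is not None:
        p = dict(model.fixed)
        p.update(params)
        a = predictor_series(model.a_kind, session.nodes, session.n_nodes, p)
        mu += params["beta_A"] * a
        if include_nuisance:
            mu += params.get("beta_ntrials", 0.0) * session.r_ntrials
            mu += params.get("beta_lag10", 0.0) * session.r_lag10
    if model.has_recency:
        w = _kernels.recency_series(
            np.ascontiguousarray(session.nodes, dtype=np.int64),
            session.n_nodes,
            model.fixed.get("alpha_W", params.get("alpha_W")),
        )
        mu += params["beta_W"] * w
    return mu


# --------------------------------------------------------------------------
# likelihood

LOG_2PI = float(np.log(2.0 * np.pi))


def shifted_lognormal_nll(rt: np.ndarray | float, mu: np.ndarray | float,
                          sigma: float, shift: float) -> np.ndarray | float:
    """Per-trial negative log density of the shifted log-normal.

    NLL = log sigma + 0.5 log(2 pi) + log(rt - shift)
          + (log(rt - shift) - mu)^2 / (2 sigma^2);
    rt <= shift contributes +inf (the optimizer rejects such parameters).
    """
    rt = np.asarray(rt, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = rt - shift
        y = np.where(x > 0, np.log(np.maximum(x, 1e-300)), np.nan)
        nll = np.log(sigma) + 0.5 * LOG_2PI + y + (y - mu) ** 2 / (2.0 * sigma**2)
    nll = np.where(np.isfinite(nll), nll, np.inf)
    return float(nll) if nll.ndim == 0 else nll


def sequence_nll(model: ModelSpec, sessions: Session | list[Session],
                 params: dict[str, float], include_targets: bool = True,
                 include_nuisance: bool = True) -> float:
    """Total NLL of a subject's sessions under one model.

    Learner state runs over every trial of each session (resetting per
    session); likelihood sums only over included trials past the
    equilibration window.  The shift is shift_frac times the subject's
    minimum observed valid RT.
    """
    if isinstance(sessions, Session):
        sessions = [sessions]
    min_rt = min(s.min_rt for s in sessions)
    shift = params["shift_frac"] * min_rt
    total = 0.0
    for s in sessions:
        try:
            mu = mu_series(model, s, params, include_targets, include_nuisance)
        except FloatingPointError:
            return np.inf
        nll = shifted_lognormal_nll(s.rt_ms[s.lik_mask], mu[s.lik_mask],
                                    params["sigma"], shift)
        total += float(np.sum(nll))
    return total
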
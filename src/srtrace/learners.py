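"""Trial-by-trial predictive learners and closed-form successor-representation oracles.

Four learners map a node sequence to per-trial expectancy of the upcoming node:

* recency  — an exponentially weighted running average W of node frequencies,
  unconditional on the predecessor state;
* one-step — a row-wise delta rule on the conditional transition matrix T;
* SR-TD(lambda) — temporal-difference learning of the successor matrix
  M = T + gamma*T^2 + gamma^2*T^3 + ... (one-step-ahead convention) with a
  dutch eligibility trace, interpolating between pure bootstrapping
  (lambda=0) and Monte-Carlo-like trace learning (lambda=1);
* a trace-only Hebbian learner, the lambda=1 reference in which the
  bootstrap term is dropped because successive bootstrap contributions
  telescope away when the trace decays by exactly gamma.

``analytic_sr`` gives the common fixed point M = T (I - gamma T)^-1 and serves
as the convergence oracle for all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import Walk, empirical_transition_matrix


# --------------------------------------------------------------------------
# recency learner

@dataclass
class RecencyState:
    """Unconditional expectancy vector W (unit sum) with learning rate alpha."""

    W: np.ndarray
    alpha: float


def recency_init(n: int, alpha: float) -> RecencyState:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return RecencyState(W=np.full(n, 1.0 / n), alpha=alpha)


def recency_update(state: RecencyState, s_t: int) -> RecencyState:
    """W <- (1-alpha) W + alpha * onehot(s_t)."""
    w = (1.0 - state.alpha) * state.W
    w[s_t] += state.alpha
    return RecencyState(W=w, alpha=state.alpha)


# --------------------------------------------------------------------------
# one-step transition learner

@dataclass
class OneStepState:
    """Learned conditional transition estimate T (rows unit-sum)."""

    T: np.ndarray
    alpha: float


def onestep_init(n: int, alpha: float) -> OneStepState:
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return OneStepState(T=np.full((n, n), 1.0 / n), alpha=alpha)


def onestep_update(state: OneStepState, s_prev: int, s_t: int) -> OneStepState:
    """Decay row s_prev by (1-alpha), then add alpha at (s_prev, s_t)."""
    t = state.T.copy()
    t[s_prev] *= 1.0 - state.alpha
    t[s_prev, s_t] += state.alpha
    return OneStepState(T=t, alpha=state.alpha)


# --------------------------------------------------------------------------
# SR-TD(lambda)

@dataclass
class SRState:
    """Successor matrix M, dutch eligibility trace e, and learning parameters."""

    M: np.ndarray
    e: np.ndarray
    alpha: float
    gamma: float
    lam: float


def sr_init(n: int, gamma: float, alpha: float, lam: float) -> SRState:
    """M initialized at the SR of the uniform transition matrix; zero trace.

    For uniform T_u (all entries 1/n), T_u is idempotent, so the geometric
    series collapses and every entry of (I - gamma T_u)^-1 T_u is
    1 / (n (1 - gamma)).
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0,1)")
    m = np.full((n, n), 1.0 / (n * (1.0 - gamma)))
    return SRState(M=m, e=np.zeros(n), alpha=alpha, gamma=gamma, lam=lam)


def sr_td_update(state: SRState, s_prev: int, s_t: int) -> tuple[SRState, np.ndarray]:
    """One SR-TD(lambda) step with a dutch trace; returns new state and TD error.

    Order: (1) e[s_prev] <- (1-alpha) e[s_prev] + 1;
           (2) delta = onehot(s_t) + gamma M[s_t,:] - M[s_prev,:];
           (3) M[s',:] += alpha e[s'] delta for every state s';
           (4) e <- gamma lambda e.
    The current transition is itself trace-weighted because the trace is
    incremented before the update is applied.
    """
    e = state.e.copy()
    e[s_prev] = (1.0 - state.alpha) * e[s_prev] + 1.0
    delta = state.gamma * state.M[s_t] - state.M[s_prev]
    delta[s_t] += 1.0
    m = state.M + state.alpha * np.outer(e, delta)
    e = state.gamma * state.lam * e
    return SRState(M=m, e=e, alpha=state.alpha, gamma=state.gamma, lam=state.lam), delta


def sr_predictor(M: np.ndarray, s_prev: int, s_t: int) -> float:
    """Expectancy readout M[s_prev, s_t] normalized by the row sum of M[s_prev,:]."""
    row_sum = M[s_prev].sum()
    if row_sum <= 0:
        raise ValueError("nonpositive SR row sum (diverged learning?)")
    return float(M[s_prev, s_t] / row_sum)


def analytic_sr(T: np.ndarray, gamma: float) -> np.ndarray:
    """Closed-form one-step-ahead SR: M = T (I - gamma T)^-1.

    The convergence oracle for SR-TD: the fixed point of the TD update under
    the stationary walk, equal to T + gamma T^2 + gamma^2 T^3 + ...
    """
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0,1)")
    n = T.shape[0]
    return T @ np.linalg.inv(np.eye(n) - gamma * T)


def static_sr(walk: Walk | np.ndarray, gamma: float, n_nodes: int | None = None) -> np.ndarray:
    """SR of the empirical transition matrix over an entire observed sequence."""
    if isinstance(walk, Walk):
        nodes, n = walk.nodes, walk.graph.n_nodes
    else:
        nodes = np.asarray(walk)
        n = n_nodes if n_nodes is not None else int(nodes.max()) + 1
    t_hat = empirical_transition_matrix(nodes, n)
    return analytic_sr(t_hat, gamma)


# --------------------------------------------------------------------------
# trace-only Hebbian reference learner (lambda = 1)

def hebbian_trace_update(
    M: np.ndarray, e: np.ndarray, s_prev: int, s_t: int, alpha: float, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Trace-only Hebbian SR update (the lambda=1, bootstrap-free reference).

    Each trial: the predecessor's dutch trace is incremented, the predecessor's
    row forgets at rate alpha (the regression toward a fresh discounted-return
    sample), every eligible state credits the encountered node in proportion
    to its trace, and the trace decays by gamma.  In expectation the fixed
    point is the one-step-ahead SR up to the slight row rescaling the dutch
    increment introduces; the readout normalization of ``sr_predictor``
    removes that rescaling.
    """
    m = M.copy()
    e = e.copy()
    e[s_prev] = (1.0 - alpha) * e[s_prev] + 1.0
    m[s_prev] *= 1.0 - alpha
    m[:, s_t] += alpha * e
    e *= gamma
    return m, e


def run_hebbian_trace(
    nodes: np.ndarray, n: int, alpha: float, gamma: float, M0: np.ndarray | None = None
) -> np.ndarray:
    """Run the Hebbian trace learner over a node sequence; returns final M."""
    m = np.zeros((n, n)) if M0 is None else M0.copy()
    e = np.zeros(n)
    for t in range(1, len(nodes)):
        m, e = hebbian_trace_update(m, e, int(nodes[t - 1]), int(nodes[t]), alpha, gamma)
    return m


def bootstrap_cancellation_terms(
    M: np.ndarray, nodes: np.ndarray, alpha: float, gamma: float
) -> dict[str, np.ndarray]:
    """Decompose accumulated SR-TD(1) updates at a frozen M into trace vs bootstrap parts.

    With lambda=1 the trace decays by exactly gamma, so the bootstrap
    components gamma*M[s_t,:] - M[s_{t-1},:] of successive trace-weighted
    updates telescope: summed along the walk they reduce to the per-impulse
    forgetting terms -c_t M[s_{t-1},:] (exactly the Hebbian learner's
    forgetting) plus an end-boundary term that carries a factor gamma^k for a
    trace k steps old.  Evaluated at a frozen M (first order in alpha), the
    identity is exact up to that boundary term.

    Returns the accumulated bootstrap sum, the Hebbian forgetting sum, the
    exact end-boundary matrix, and the full TD(1) and Hebbian accumulations.
    """
    n = M.shape[0]
    e = np.zeros(n)
    boot = np.zeros((n, n))
    forget = np.zeros((n, n))
    hebb = np.zeros((n, n))
    td = np.zeros((n, n))
    impulses: list[tuple[int, float, int]] = []  # (state, increment, trial)
    for t in range(1, len(nodes)):
        sp, st = int(nodes[t - 1]), int(nodes[t])
        c = 1.0 - alpha * e[sp]  # dutch increment amount
        e[sp] += c
        impulses.append((sp, c, t))
        delta_boot = gamma * M[st] - M[sp]
        boot += alpha * np.outer(e, delta_boot)
        td += alpha * np.outer(e, delta_boot)
        onehot = np.zeros(n)
        onehot[st] = 1.0
        td += alpha * np.outer(e, onehot)
        hebb += alpha * np.outer(e, onehot)
        fr = np.zeros((n, n))
        fr[sp] = -alpha * c * M[sp]
        forget += fr
        hebb += fr
        e *= gamma
    t_end = len(nodes) - 1
    boundary = np.zeros((n, n))
    for sp, c, t in impulses:
        boundary[sp] += alpha * c * gamma ** (t_end - t + 1) * M[int(nodes[t_end])]
    return {
        "bootstrap_sum": boot,
        "forgetting_sum": forget,
        "boundary": boundary,
        "td1_accum": td,
        "hebbian_accum": hebb,
    }


def horizon(gamma: float) -> float:
    """Effective temporal horizon of discount gamma: 1 / (1 - gamma) timesteps."""
    if not 0 <= gamma < 1:
        raise ValueError("gamma must be in [0,1)")
    return 1.0 / (1.0 - gamma)
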
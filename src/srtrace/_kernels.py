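"""Numba-compiled forward passes over node sequences.

These mirror the stateful reference implementations in ``learners`` (the
equivalence is tested) and exist because model fitting evaluates the
per-trial predictor series thousands of times per subject.  Each function
returns the predictor value for trial t computed from the learner state
*before* observing trial t, which is the quantity that can legitimately
drive the reaction time on that trial.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# |M| entries beyond this are treated as divergence; the likelihood at such a
# parameter point is returned as +inf so the optimizer rejects it.
M_DIVERGENCE_LIMIT = 1.0e3


@njit(cache=False)
def recency_series(nodes: np.ndarray, n: int, alpha: float) -> np.ndarray:
    """Per-trial W[s_t] for the exponential recency learner, W0 uniform."""
    T = nodes.shape[0]
    w = np.full(n, 1.0 / n)
    out = np.empty(T)
    for t in range(T):
        s = nodes[t]
        out[t] = w[s]
        for j in range(n):
            w[j] *= 1.0 - alpha
        w[s] += alpha
    return out


@njit(cache=False)
def onestep_series(nodes: np.ndarray, n: int, alpha: float) -> np.ndarray:
    """Per-trial T[s_prev, s_t] for the one-step learner, T0 uniform.

    Trial 0 has no predecessor; its predictor is the uniform 1/n.
    """
    T = nodes.shape[0]
    tm = np.full((n, n), 1.0 / n)
    out = np.empty(T)
    out[0] = 1.0 / n
    for t in range(1, T):
        sp = nodes[t - 1]
        st = nodes[t]
        out[t] = tm[sp, st]
        for j in range(n):
            tm[sp, j] *= 1.0 - alpha
        tm[sp, st] += alpha
    return out


@njit(cache=False)
def srtd_series(
    nodes: np.ndarray, n: int, alpha: float, gamma: float, lam: float
) -> tuple[np.ndarray, bool]:
    """Per-trial normalized SR readout M[s_prev,s_t]/sum(M[s_prev,:]) under SR-TD(lambda).

    M starts at the SR of the uniform transition matrix; dutch eligibility
    trace; update order: trace increment, TD error, trace-broadcast update,
    trace decay.  Returns (series, ok); ok=False flags divergence.
    """
    T = nodes.shape[0]
    m = np.full((n, n), 1.0 / (n * (1.0 - gamma)))
    e = np.zeros(n)
    out = np.empty(T)
    out[0] = 1.0 / n
    gl = gamma * lam
    for t in range(1, T):
        sp = nodes[t - 1]
        st = nodes[t]
        row_sum = 0.0
        for j in range(n):
            row_sum += m[sp, j]
        if row_sum <= 0.0:
            return out, False
        out[t] = m[sp, st] / row_sum
        # dutch trace increment
        e[sp] = (1.0 - alpha) * e[sp] + 1.0
        # delta = onehot(st) + gamma*M[st,:] - M[sp,:], fixed before the broadcast
        delta = np.empty(n)
        for j in range(n):
            delta[j] = gamma * m[st, j] - m[sp, j]
        delta[st] += 1.0
        biggest = 0.0
        for sprime in range(n):
            ae = alpha * e[sprime]
            if ae != 0.0:
                for j in range(n):
                    m[sprime, j] += ae * delta[j]
        for i in range(n):
            for j in range(n):
                if abs(m[i, j]) > biggest:
                    biggest = abs(m[i, j])
        if biggest > M_DIVERGENCE_LIMIT:
            return out, False
        for j in range(n):
            e[j] *= gl
    return out, True


@njit(cache=False)
def srtd_run(
    nodes: np.ndarray,
    n: int,
    alpha: float,
    gamma: float,
    lam: float,
    avg_last: int,
) -> np.ndarray:
    """Run SR-TD(lambda) over a walk; return M averaged over the final ``avg_last`` steps."""
    T = nodes.shape[0]
    m = np.full((n, n), 1.0 / (n * (1.0 - gamma)))
    e = np.zeros(n)
    acc = np.zeros((n, n))
    n_acc = 0
    gl = gamma * lam
    for t in range(1, T):
        sp = nodes[t - 1]
        st = nodes[t]
        e[sp] = (1.0 - alpha) * e[sp] + 1.0
        delta = np.empty(n)
        for j in range(n):
            delta[j] = gamma * m[st, j] - m[sp, j]
        delta[st] += 1.0
        for sprime in range(n):
            ae = alpha * e[sprime]
            if ae != 0.0:
                for j in range(n):
                    m[sprime, j] += ae * delta[j]
        for j in range(n):
            e[j] *= gl
        if t > T - 1 - avg_last:
            acc += m
            n_acc += 1
    if n_acc == 0:
        return m
    return acc / n_acc


@njit(cache=False)
def hebbian_run(
    nodes: np.ndarray, n: int, alpha: float, gamma: float, avg_last: int
) -> np.ndarray:
    """Run the trace-only Hebbian learner; return M averaged over the final steps."""
    T = nodes.shape[0]
    m = np.zeros((n, n))
    e = np.zeros(n)
    acc = np.zeros((n, n))
    n_acc = 0
    for t in range(1, T):
        sp = nodes[t - 1]
        st = nodes[t]
        e[sp] = (1.0 - alpha) * e[sp] + 1.0
        for j in range(n):
            m[sp, j] *= 1.0 - alpha
        for i in range(n):
            m[i, st] += alpha * e[i]
        for j in range(n):
            e[j] *= gamma
        if t > T - 1 - avg_last:
            acc += m
            n_acc += 1
    if n_acc == 0:
        return m
    return acc / n_acc


@njit(cache=False)
def hebbian_series(
    nodes: np.ndarray, n: int, alpha: float, gamma: float
) -> np.ndarray:
    """Per-trial normalized readout of the trace-only Hebbian (lambda=1) learner."""
    T = nodes.shape[0]
    m = np.full((n, n), 1.0 / (n * (1.0 - gamma)))
    e = np.zeros(n)
    out = np.empty(T)
    out[0] = 1.0 / n
    for t in range(1, T):
        sp = nodes[t - 1]
        st = nodes[t]
        row_sum = 0.0
        for j in range(n):
            row_sum += m[sp, j]
        out[t] = m[sp, st] / row_sum if row_sum > 0 else 1.0 / n
        e[sp] = (1.0 - alpha) * e[sp] + 1.0
        for j in range(n):
            m[sp, j] *= 1.0 - alpha
        for i in range(n):
            m[i, st] += alpha * e[i]
        for j in range(n):
            e[j] *= gamma
    return out
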
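"""Model-agnostic sequence-pattern signatures of trace and bootstrap updating.

Eligibility-trace learning predicts that after S -> X -> T the expectancy of
T from S is already strengthened, so on the closing S -> T of an 'SXTST'
window the response should be faster than on the matched control
'X1X2TST' (same recency of T and S, no possible trace update for S -> T).
Bootstrap (TD(0)) learning instead predicts facilitation on the closing
S -> T of 'BTSBST' relative to 'XTSBST': the early B -> T strengthens T-from-B,
and the later S -> B backs that prediction up to S.  Reaction-time contrasts
between test and control windows are therefore signatures of the respective
update mechanisms that require no model fitting.

The cluster-entry analysis tests a successor-representation prediction on the
modular graph: the second node after entering a new cluster is responded to
faster than the first, a pattern an unconditional recency learner does not
produce.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .graphs import Graph
from .rt_model import (
    MODELS,
    Session,
    mu_series,
    preprocess,
    sessions_from_table,
)
from .hierarchical import FitOptions, GroupModel, default_group_init, subject_map_fit

log = logging.getLogger(__name__)

PATTERN_KINDS = ("trace_test", "trace_control", "bootstrap_test", "bootstrap_control")


@dataclass(frozen=True)
class PatternMatch:
    subject: str
    graphset: str
    end_trial: int  # 0-based index of the final pattern element
    kind: str
    rt: float
    target: int


# --------------------------------------------------------------------------
# pattern finders

def find_trace_patterns(nodes: np.ndarray) -> list[tuple[int, str]]:
    """All 5-windows matching S,X,T,S,T (test) or X1,X2,T,S,T (control).

    Returns (end_index, kind) for every window; overlapping windows all
    count.  Test: S==w[3], T==w[2]==w[4], S, X, T pairwise distinct.
    Control: T==w[2]==w[4], S=w[3] != T, w[0] and w[1] both outside {S, T},
    and the window does not match the test template (w[0] != S).  The two
    fillers may coincide; only the recency of S must be broken.
    """
    nodes = np.asarray(nodes, dtype=np.int64)
    out = []
    for end in range(4, len(nodes)):
        w = nodes[end - 4 : end + 1]
        t, s = w[4], w[3]
        if w[2] != t or s == t:
            continue
        if w[0] == s and w[1] not in (s, t):
            out.append((end, "trace_test"))
        elif w[0] not in (s, t) and w[1] not in (s, t):
            out.append((end, "trace_control"))
    return out


def find_bootstrap_patterns(nodes: np.ndarray) -> list[tuple[int, str]]:
    """All 6-windows matching B,T,S,B,S,T (test) or X,T,S,B,S,T (control).

    Test: B==w[0]==w[3], S==w[2]==w[4], T==w[1]==w[5], B, T, S pairwise
    distinct.  Control: same closing structure with w[0] outside {B, T, S}.
    """
    nodes = np.asarray(nodes, dtype=np.int64)
    out = []
    for end in range(5, len(nodes)):
        w = nodes[end - 5 : end + 1]
        t, s, b = w[5], w[4], w[3]
        if w[1] != t or w[2] != s:
            continue
        if len({b, t, s}) != 3:
            continue
        if w[0] == b:
            out.append((end, "bootstrap_test"))
        elif w[0] not in (b, t, s):
            out.append((end, "bootstrap_control"))
    return out


def collect_pattern_matches(df: pd.DataFrame, contrast: str = "trace") -> pd.DataFrame:
    """Scan every session of a (preprocessed) trial table for pattern windows.

    Patterns are matched on the raw node sequence, including trials excluded
    from likelihood (perception sees every stimulus), but a match whose final
    element has an invalid RT is dropped.  Windows may span the equilibration
    boundary; sessions are separate sequences.
    """
    if "include" not in df.columns:
        df = preprocess(df)
    finder = find_trace_patterns if contrast == "trace" else find_bootstrap_patterns
    rows = []
    for (subj, gs, stage), g in df.groupby(["subject", "graphset", "stage"], sort=True):
        nodes = g["node"].to_numpy(dtype=np.int64) - 1
        rt = g["rt_ms"].to_numpy(dtype=float)
        target = g["target"].to_numpy(dtype=np.int64)
        include = g["include"].to_numpy(dtype=bool)
        for end, kind in finder(nodes):
            if not include[end]:
                continue
            rows.append(
                {
                    "subject": subj,
                    "graphset": f"{gs}/{stage}",
                    "end_trial": end,
                    "kind": kind,
                    "rt_ms": rt[end],
                    "target": int(target[end]),
                }
            )
    return pd.DataFrame(rows, columns=["subject", "graphset", "end_trial", "kind", "rt_ms", "target"])


# --------------------------------------------------------------------------
# mixed-effects contrasts

@dataclass
class ContrastResult:
    effect_estimate: float  # RT difference attributable to the test pattern (ms)
    se: float
    z_or_t: float
    p: float
    n_obs: int
    fallback: str = "none"  # none | intercept_only | ols


def _fit_mixed(df: pd.DataFrame, formula: str, re_formula: str, vc: dict | None,
               groups: str, indicator: str) -> tuple[object, str]:
    """MixedLM with random slopes; falls back to intercepts, then to OLS."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            m = smf.mixedlm(formula, df, groups=df[groups], re_formula=re_formula,
                            vc_formula=vc).fit(reml=True, method="lbfgs", maxiter=200)
            if np.isfinite(m.bse[indicator]) and m.bse[indicator] > 0:
                return m, "none"
        except Exception:
            pass
        try:
            m = smf.mixedlm(formula, df, groups=df[groups]).fit(
                reml=True, method="lbfgs", maxiter=200)
            if np.isfinite(m.bse[indicator]) and m.bse[indicator] > 0:
                return m, "intercept_only"
        except Exception:
            pass
        m = smf.ols(formula, df).fit()
        return m, "ols"


def signature_contrast(matches: pd.DataFrame, contrast: str = "trace") -> ContrastResult:
    """Hierarchical contrast of test vs control final-element reaction times.

    Fits rt ~ indicator + motor-target offsets with random intercept and
    indicator slope by subject, and a graphset variance component when more
    than one graphset is present.  The indicator codes the test pattern, so a
    negative estimate is RT facilitation.  Fit on untransformed RT in ms.
    """
    test_kind = f"{contrast}_test"
    df = matches.copy()
    df["is_test"] = (df["kind"] == test_kind).astype(float)
    if df["subject"].nunique() < 2 or df["is_test"].nunique() < 2:
        raise ValueError("need >= 2 subjects with matches of both kinds")
    n_targets = df["target"].nunique()
    formula = "rt_ms ~ is_test" + (" + C(target)" if n_targets > 1 else "")
    vc = None
    if df.groupby("subject")["graphset"].nunique().max() > 1:
        vc = {"graphset": "0 + C(graphset)"}
    model, fallback = _fit_mixed(df, formula, "1 + is_test", vc, "subject", "is_test")
    if fallback != "none":
        log.info("signature_contrast: random-effects fallback -> %s", fallback)
    return ContrastResult(
        effect_estimate=float(model.params["is_test"]),
        se=float(model.bse["is_test"]),
        z_or_t=float(model.params["is_test"] / model.bse["is_test"]),
        p=float(model.pvalues["is_test"]),
        n_obs=len(df),
        fallback=fallback,
    )


# --------------------------------------------------------------------------
# residualized RTs and the novel-cluster analysis

def residualize_rts(df: pd.DataFrame, opts: FitOptions | None = None) -> pd.DataFrame:
    """Residual log shifted RTs after a baseline fit (trial + motor terms only).

    Fits the baseline observation model (mu0, trial slope, target offsets,
    shift, sigma) per session under a weak default prior and returns the
    table restricted to likelihood-included trials with a ``resid`` column:
    log(rt - shift) - mu_t.
    """
    if "include" not in df.columns:
        df = preprocess(df)
    opts = opts or FitOptions(n_restarts=1, compute_laplace=False)
    model = MODELS["baseline"]
    sessions = sessions_from_table(df)
    out = []
    group0 = default_group_init(model, sessions, opts)
    for s in sessions:
        fit = subject_map_fit(model, s, group0, opts, seed=0)
        params = fit.params_natural
        mu = mu_series(model, s, params, opts.include_targets, opts.include_nuisance)
        shift = params["shift_frac"] * s.min_rt
        resid = np.full(len(s.nodes), np.nan)
        m = s.lik_mask
        resid[m] = np.log(s.rt_ms[m] - shift) - mu[m]
        out.append(
            pd.DataFrame(
                {
                    "subject": s.subject,
                    "graphset": s.graphset,
                    "stage": s.stage,
                    "t_index": np.arange(len(s.nodes)),
                    "node": s.nodes,
                    "resid": resid,
                    "valid": m,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


MAX_LAG = 100


def cluster_entry_rows(nodes: np.ndarray, graph: Graph) -> list[tuple[int, int, int]]:
    """(t_index, cluster_step, lag) for 1st/2nd nodes after a cross-cluster entry.

    cluster_step is 0 for the entry node, 1 for the following node when it
    stays in the new cluster; lag is trials since the node was last seen,
    capped at MAX_LAG (first occurrences count as the cap).
    """
    cl = np.array([graph.cluster_of[int(u)] for u in nodes])
    last_seen: dict[int, int] = {}
    lags = np.empty(len(nodes), dtype=int)
    for t, s in enumerate(nodes):
        s = int(s)
        lags[t] = min(t - last_seen[s], MAX_LAG) if s in last_seen else MAX_LAG
        last_seen[s] = t
    rows = []
    for t in range(1, len(nodes)):
        if cl[t] != cl[t - 1]:  # first entry into a new cluster
            rows.append((t, 0, int(lags[t])))
            if t + 1 < len(nodes) and cl[t + 1] == cl[t]:
                rows.append((t + 1, 1, int(lags[t + 1])))
    return rows


def cluster_entry_analysis(df: pd.DataFrame, graph: Graph,
                           opts: FitOptions | None = None) -> ContrastResult:
    """First- vs second-entry RT contrast on the modular graph.

    Residualizes RTs per session (trial and motor terms only), finds first
    and second nodes after every cross-cluster transition, and fits
    resid ~ C(lag, Sum) + cluster_step with a random intercept and
    cluster_step slope by subject; lag (trials since the node last occurred,
    capped at 100) is an effects-coded categorical recency control.  A
    negative cluster_step estimate means the second entry is faster.
    """
    if graph.cluster_of is None:
        raise ValueError("cluster analysis requires a modular graph")
    resid = residualize_rts(df, opts)
    rows = []
    for (subj, gs, stage), g in resid.groupby(["subject", "graphset", "stage"], sort=True):
        g = g.sort_values("t_index")
        nodes = g["node"].to_numpy()
        valid = g["valid"].to_numpy()
        rvals = g["resid"].to_numpy()
        for t, step, lag in cluster_entry_rows(nodes, graph):
            if valid[t]:
                rows.append({"subject": subj, "resid": rvals[t],
                             "cluster_step": step, "lag": lag})
    data = pd.DataFrame(rows)
    if len(data) == 0:
        raise ValueError("no cross-cluster entry events found")
    formula = "resid ~ C(lag, Sum) + cluster_step"
    model, fallback = _fit_mixed(data, formula, "1 + cluster_step", None,
                                 "subject", "cluster_step")
    if fallback != "none":
        log.info("cluster_entry_analysis: random-effects fallback -> %s", fallback)
    return ContrastResult(
        effect_estimate=float(model.params["cluster_step"]),
        se=float(model.bse["cluster_step"]),
        z_or_t=float(model.params["cluster_step"] / model.bse["cluster_step"]),
        p=float(model.pvalues["cluster_step"]),
        n_obs=len(data),
        fallback=fallback,
    )
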
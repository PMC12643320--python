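"""Hierarchical model fitting by EM with Laplace-approximated marginal likelihoods.

Each session's parameters are fit by MAP estimation under a Gaussian
population prior with identity covariance on an unconstrained scale (logit
for rates, discount, trace decay and shift fraction; log for sigma; identity
for the baseline, slopes and offsets).  An expectation-maximization loop
alternates MAP fits (E-step) with a least-squares update of the group mean
and stage-difference coefficients (M-step; the covariance stays the
identity).  Model evidence per session is a Laplace approximation to the
negative log marginal likelihood, and models are compared by paired t-tests
on per-session scores after an equally shared AIC penalty for the
group-level parameters.

For speed, the MAP objective is profiled: given the nonlinear block (learner
parameters, shift fraction, sigma) the linear coefficients have a closed-form
ridge solution, so the optimizer only searches the low-dimensional nonlinear
space.  Learner predictor series are cached by learner-parameter value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import _kernels
from .rt_model import (
    ModelSpec,
    Session,
    linear_param_names,
    param_names,
    predictor_series,
)

log = logging.getLogger(__name__)

LOG_2PI = float(np.log(2.0 * np.pi))

# parameters constrained to (0,1) -> logit; positive -> log; rest identity
LOGIT_PARAMS = {"alpha_A", "alpha_W", "gamma", "lam", "shift_frac"}
LOG_PARAMS = {"sigma"}
UNCONSTRAINED_BOUND = 16.0  # |logit|/|log| cap, keeps exp() finite


def to_unconstrained(name: str, x: float) -> float:
    if name in LOGIT_PARAMS:
        x = min(max(x, 1e-7), 1 - 1e-7)
        return float(np.log(x / (1.0 - x)))
    if name in LOG_PARAMS:
        return float(np.log(x))
    return float(x)


def to_natural(name: str, z: float) -> float:
    if name in LOGIT_PARAMS:
        return float(1.0 / (1.0 + np.exp(-z)))
    if name in LOG_PARAMS:
        return float(np.exp(z))
    return float(z)


def vector_to_natural(names: list[str], z: np.ndarray) -> dict[str, float]:
    return {n: to_natural(n, v) for n, v in zip(names, z)}


def vector_to_unconstrained(names: list[str], params: dict[str, float]) -> np.ndarray:
    return np.array([to_unconstrained(n, params[n]) for n in names])


@dataclass
class FitOptions:
    """Optimizer and EM controls."""

    include_targets: bool = True
    include_nuisance: bool = True
    n_restarts: int = 3  # prior-mean start plus jittered starts
    restart_scale: float = 0.5
    em_max_iter: int = 50
    em_tol: float = 1e-3
    aic_unit: float = 1.0  # NLL units charged per group-level parameter
    seed: int = 0
    compute_laplace: bool = True
    hessian_step: float = 1e-3


@dataclass
class GroupModel:
    """Population-level Gaussian with identity covariance on the unconstrained scale."""

    names: list[str]
    group_mean: np.ndarray
    stage_coef: np.ndarray

    def prior_mean(self, stage_covariate: float) -> np.ndarray:
        return self.group_mean + stage_covariate * self.stage_coef

    def natural_means(self) -> dict[str, float]:
        return vector_to_natural(self.names, self.group_mean)


@dataclass
class SubjectFit:
    """MAP fit of one session."""

    subject: str
    graphset: str
    stage: int
    names: list[str]
    theta_map: np.ndarray  # unconstrained
    neg_log_post: float  # incl. prior quadratic and prior normalizer
    converged: bool
    hessian: np.ndarray | None = None
    laplace_nlml: float | None = None

    @property
    def params_natural(self) -> dict[str, float]:
        return vector_to_natural(self.names, self.theta_map)


# --------------------------------------------------------------------------
# MAP objective for one session group (one fitting unit)

class MapObjective:
    """Negative log posterior of one fitting unit, with profiled linear block.

    Parameter order is the canonical ``param_names`` order: linear
    coefficients first, then learner parameters, shift fraction and sigma.
    """

    def __init__(self, model: ModelSpec, sessions: list[Session], opts: FitOptions,
                 prior_mean: np.ndarray):
        self.model = model
        self.sessions = sessions
        self.opts = opts
        self.names = param_names(model, opts.include_targets, opts.include_nuisance)
        self.lin_names = linear_param_names(model, opts.include_targets, opts.include_nuisance)
        self.nonlin_names = [n for n in self.names if n not in self.lin_names]
        self.n_lin = len(self.lin_names)
        self.dim = len(self.names)
        self.prior_mean = np.asarray(prior_mean, dtype=float)
        if self.prior_mean.shape != (self.dim,):
            raise ValueError("prior mean has wrong dimension")
        self.min_rt = min(s.min_rt for s in sessions)
        self._series_cache: dict[tuple, tuple] = {}
        self._a_col = self.lin_names.index("beta_A") if "beta_A" in self.lin_names else -1
        self._w_col = self.lin_names.index("beta_W") if "beta_W" in self.lin_names else -1
        # design columns that do not depend on nonlinear parameters
        self._base: list[np.ndarray] = []
        self._rt_inc: list[np.ndarray] = []
        for s in sessions:
            mask = s.lik_mask
            cols = []
            for nm in self.lin_names:
                if nm == "mu0":
                    cols.append(np.ones(mask.sum()))
                elif nm == "beta_trial":
                    cols.append(s.trial_scaled[mask])
                elif nm.startswith("target_"):
                    k = int(nm.split("_")[1])
                    cols.append((s.targets[mask] == k - 1).astype(float))
                elif nm == "beta_ntrials":
                    cols.append(s.r_ntrials[mask])
                elif nm == "beta_lag10":
                    cols.append(s.r_lag10[mask])
                elif nm in ("beta_A", "beta_W"):
                    cols.append(np.zeros(mask.sum()))  # filled per eval
                else:
                    raise AssertionError(nm)
            self._base.append(np.column_stack(cols))
            self._rt_inc.append(s.rt_ms[mask])
        self.n_obs = int(sum(len(r) for r in self._rt_inc))

    # -- learner series ----------------------------------------------------
    def _learner_series(self, nonlin: dict[str, float]) -> list[tuple[np.ndarray | None, np.ndarray | None]]:
        """(A, W) series per session on included trials; cached by learner params."""
        keys = tuple(
            round(nonlin[p] if p not in self.model.fixed else self.model.fixed[p], 14)
            for p in ("alpha_A", "alpha_W", "gamma", "lam")
            if p in nonlin or p in self.model.fixed
        )
        hit = self._series_cache.get(keys)
        if hit is not None:
            return hit
        out = []
        p = dict(self.model.fixed)
        p.update(nonlin)
        for s in self.sessions:
            a = w = None
            if self.model.a_kind is not None:
                a = predictor_series(self.model.a_kind, s.nodes, s.n_nodes, p)[s.lik_mask]
            if self.model.has_recency:
                w = _kernels.recency_series(
                    np.ascontiguousarray(s.nodes, dtype=np.int64), s.n_nodes,
                    p["alpha_W"])[s.lik_mask]
            out.append((a, w))
        self._series_cache[keys] = out
        return out

    def _design(self, nonlin: dict[str, float]) -> tuple[np.ndarray, np.ndarray] | None:
        """Stacked (X, y) over sessions for the current nonlinear block."""
        shift = nonlin["shift_frac"] * self.min_rt
        try:
            series = self._learner_series(nonlin)
        except FloatingPointError:
            return None
        xs, ys = [], []
        for base, rt, (a, w) in zip(self._base, self._rt_inc, series):
            x = base.copy()
            if a is not None:
                x[:, self._a_col] = a
            if w is not None:
                x[:, self._w_col] = w
            xs.append(x)
            ys.append(np.log(rt - shift))  # rt > shift holds: shift < min valid rt
        return np.vstack(xs), np.concatenate(ys)

    def _nonlin_dict(self, phi: np.ndarray) -> dict[str, float]:
        return {n: to_natural(n, v) for n, v in zip(self.nonlin_names, phi)}

    # -- full objective ----------------------------------------------------
    def full_value(self, theta: np.ndarray) -> float:
        """Negative log posterior at a full unconstrained parameter vector."""
        beta = theta[: self.n_lin]
        phi = theta[self.n_lin:]
        nonlin = self._nonlin_dict(phi)
        dxy = self._design(nonlin)
        if dxy is None:
            return np.inf
        x, y = dxy
        sigma = nonlin["sigma"]
        resid = y - x @ beta
        nll = (
            self.n_obs * (np.log(sigma) + 0.5 * LOG_2PI)
            + float(np.sum(y))
            + float(resid @ resid) / (2.0 * sigma**2)
        )
        dz = theta - self.prior_mean
        return nll + 0.5 * float(dz @ dz) + 0.5 * self.dim * LOG_2PI

    # -- profiled objective ------------------------------------------------
    # large finite penalty for rejected parameter points keeps finite-difference
    # gradients well defined for the optimizer
    REJECT_VALUE = 1.0e10

    def profile_value(self, phi: np.ndarray) -> tuple[float, np.ndarray | None]:
        """Exact inner ridge minimization over the linear block given phi."""
        if np.any(np.abs(phi) > UNCONSTRAINED_BOUND):
            return self.REJECT_VALUE, None
        nonlin = self._nonlin_dict(phi)
        dxy = self._design(nonlin)
        if dxy is None:
            return self.REJECT_VALUE, None
        x, y = dxy
        sigma = nonlin["sigma"]
        m_lin = self.prior_mean[: self.n_lin]
        s2 = sigma**2
        h = x.T @ x / s2 + np.eye(self.n_lin)
        g = x.T @ y / s2 + m_lin
        beta = np.linalg.solve(h, g)
        resid = y - x @ beta
        nll = (
            self.n_obs * (np.log(sigma) + 0.5 * LOG_2PI)
            + float(np.sum(y))
            + float(resid @ resid) / (2.0 * s2)
        )
        db = beta - m_lin
        dphi = phi - self.prior_mean[self.n_lin:]
        value = nll + 0.5 * float(db @ db) + 0.5 * float(dphi @ dphi) \
            + 0.5 * self.dim * LOG_2PI
        return value, beta

    def fit(self, seed: int, n_restarts: int | None = None,
            x0: np.ndarray | None = None) -> tuple[np.ndarray, float, bool]:
        """Multi-start quasi-Newton MAP fit; returns (theta, value, success)."""
        opts = self.opts
        n_restarts = opts.n_restarts if n_restarts is None else n_restarts
        rng = np.random.default_rng(seed)
        phi0 = self.prior_mean[self.n_lin:].copy()
        starts = [phi0 if x0 is None else x0[self.n_lin:].copy()]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(phi0 + opts.restart_scale * rng.standard_normal(len(phi0)))
        best = (None, np.inf, False)
        for start in starts:
            res = optimize.minimize(
                lambda p: self.profile_value(p)[0], start, method="L-BFGS-B",
                bounds=[(-UNCONSTRAINED_BOUND, UNCONSTRAINED_BOUND)] * len(phi0),
                options={"maxiter": 200},
            )
            if res.fun < best[1]:
                best = (res.x, res.fun, bool(res.success))
        phi, value, ok = best
        if phi is None:
            raise RuntimeError("all restarts failed")
        _, beta = self.profile_value(phi)
        theta = np.concatenate([beta, phi])
        return theta, value, ok

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        """Central finite-difference Hessian of the full negative log posterior."""
        h = self.opts.hessian_step
        d = self.dim
        f = self.full_value
        hess = np.empty((d, d))
        f0 = f(theta)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h
            fp = f(theta + ei)
            fm = f(theta - ei)
            hess[i, i] = (fp - 2.0 * f0 + fm) / h**2
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h
            for j in range(i + 1, d):
                ej = np.zeros(d)
                ej[j] = h
                fpp = f(theta + ei + ej)
                fpm = f(theta + ei - ej)
                fmp = f(theta - ei + ej)
                fmm = f(theta - ei - ej)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h**2)
        return 0.5 * (hess + hess.T)


# --------------------------------------------------------------------------
# Laplace evidence, EM, comparison

def laplace_nlml(neg_log_post: float, hessian: np.ndarray, dim: int) -> tuple[float, bool]:
    """Laplace approximation to the negative log marginal likelihood.

    NLML = negLogPost(theta_map) - (dim/2) log(2 pi) + 0.5 log det(H).
    Returns (nlml, hessian_pd); a non-PD Hessian is eigenvalue-clipped at
    1e-8 and flagged.
    """
    if dim == 0:
        return neg_log_post, True
    eigs = np.linalg.eigvalsh(hessian)
    pd = bool(eigs.min() > 0)
    logdet = float(np.sum(np.log(np.clip(eigs, 1e-8, None))))
    return neg_log_post - 0.5 * dim * LOG_2PI + 0.5 * logdet, pd


def subject_map_fit(model: ModelSpec, sessions: Session | list[Session],
                    prior: GroupModel, opts: FitOptions | None = None,
                    seed: int = 0, x0: np.ndarray | None = None,
                    n_restarts: int | None = None) -> SubjectFit:
    """MAP fit of one fitting unit (typically one subject x stage session)."""
    if isinstance(sessions, Session):
        sessions = [sessions]
    opts = opts or FitOptions()
    c = sessions[0].stage_covariate
    obj = MapObjective(model, sessions, opts, prior.prior_mean(c))
    theta, value, ok = obj.fit(seed=seed, x0=x0, n_restarts=n_restarts)
    fit = SubjectFit(
        subject=sessions[0].subject, graphset=sessions[0].graphset,
        stage=sessions[0].stage, names=obj.names, theta_map=theta,
        neg_log_post=value, converged=ok,
    )
    if opts.compute_laplace:
        fit.hessian = obj.hessian(theta)
        nlml, pd = laplace_nlml(value, fit.hessian, obj.dim)
        fit.laplace_nlml = nlml
        fit.converged = fit.converged and pd
    return fit


def default_group_init(model: ModelSpec, sessions: list[Session],
                       opts: FitOptions) -> GroupModel:
    """Data-informed starting point for the group mean; stage coefficients zero."""
    names = param_names(model, opts.include_targets, opts.include_nuisance)
    med_rt = float(np.median(np.concatenate([s.rt_ms[s.include] for s in sessions])))
    min_rt = min(s.min_rt for s in sessions)
    start_natural = {
        "mu0": float(np.log(max(med_rt - 0.5 * min_rt, 10.0))),
        "beta_trial": 0.0, "beta_A": 0.0, "beta_W": 0.0,
        "beta_ntrials": 0.0, "beta_lag10": 0.0,
        "alpha_A": 0.1, "alpha_W": 0.1, "gamma": 0.5, "lam": 0.5,
        "shift_frac": 0.5, "sigma": 0.3,
    }
    mean = np.array([
        to_unconstrained(n, start_natural.get(n, 0.0)) for n in names
    ])
    return GroupModel(names=names, group_mean=mean, stage_coef=np.zeros(len(names)))


@dataclass
class EMResult:
    group: GroupModel
    fits: list[SubjectFit]
    n_iter: int
    converged: bool
    mean_history: list[np.ndarray] = field(default_factory=list)


def em_fit(model: ModelSpec, sessions: list[Session], opts: FitOptions | None = None,
           init: GroupModel | None = None) -> EMResult:
    """Hierarchical EM over fitting units.

    E-step: MAP fit per unit under the current group prior (warm-started from
    the previous iteration's MAP after the first pass).  M-step: least-squares
    regression of the MAP vectors on [1, stage_covariate] updates the group
    mean and stage coefficients; the prior covariance stays the identity.
    """
    opts = opts or FitOptions()
    if len(sessions) < 2:
        raise ValueError("em_fit requires at least 2 fitting units")
    group = init or default_group_init(model, sessions, opts)
    names = group.names
    cvec = np.array([s.stage_covariate for s in sessions])
    vary_stage = len(np.unique(cvec)) > 1
    rng = np.random.default_rng(opts.seed)
    warm: list[np.ndarray | None] = [None] * len(sessions)
    history = []
    converged = False
    it = 0
    fit_opts = FitOptions(**{**opts.__dict__, "compute_laplace": False})
    for it in range(1, opts.em_max_iter + 1):
        thetas = np.empty((len(sessions), len(names)))
        for i, s in enumerate(sessions):
            n_restarts = opts.n_restarts if it == 1 else 1
            f = subject_map_fit(
                model, s, group, fit_opts, seed=int(rng.integers(2**31)),
                x0=warm[i], n_restarts=n_restarts,
            )
            warm[i] = f.theta_map
            thetas[i] = f.theta_map
        if vary_stage:
            design = np.column_stack([np.ones(len(sessions)), cvec])
            coef, *_ = np.linalg.lstsq(design, thetas, rcond=None)
            new_mean, new_stage = coef[0], coef[1]
        else:
            new_mean, new_stage = thetas.mean(axis=0), np.zeros(len(names))
        delta = float(np.max(np.abs(new_mean - group.group_mean)))
        group = GroupModel(names=names, group_mean=new_mean, stage_coef=new_stage)
        history.append(new_mean.copy())
        if delta < opts.em_tol:
            converged = True
            break
    if not converged:
        log.warning("em_fit: no convergence in %d iterations", opts.em_max_iter)
    # final E-step under the converged prior, with Laplace evidence if requested
    fits = []
    for i, s in enumerate(sessions):
        fits.append(
            subject_map_fit(model, s, group, opts, seed=int(rng.integers(2**31)),
                            x0=warm[i], n_restarts=1)
        )
    n_bad = sum(not f.converged for f in fits)
    if n_bad:
        log.info("em_fit: %d non-converged unit fits (refitting with extra restarts)", n_bad)
        for i, f in enumerate(fits):
            if not f.converged:
                fits[i] = subject_map_fit(
                    model, sessions[i], group, opts,
                    seed=int(rng.integers(2**31)), x0=f.theta_map, n_restarts=5)
    return EMResult(group=group, fits=fits, n_iter=it, converged=converged,
                    mean_history=history)


def n_group_params(group: GroupModel, vary_stage: bool) -> int:
    d = len(group.names)
    return 2 * d if vary_stage else d


@dataclass
class ModelScore:
    model_id: str
    per_subject_score: np.ndarray
    subjects: list[str]


def model_score(result: EMResult, model_id: str = "", aic_unit: float = 1.0) -> ModelScore:
    """Per-session fit score: Laplace NLML plus an equal share of the group AIC penalty."""
    nlmls = np.array([f.laplace_nlml for f in result.fits], dtype=float)
    if np.any(np.isnan(nlmls)):
        raise ValueError("model_score requires Laplace NLMLs (compute_laplace=True)")
    vary = len({f.stage for f in result.fits}) > 1
    penalty = aic_unit * n_group_params(result.group, vary) / len(result.fits)
    return ModelScore(
        model_id=model_id,
        per_subject_score=nlmls + penalty,
        subjects=[f"{f.subject}/{f.graphset}/{f.stage}" for f in result.fits],
    )


def compare_models(scores_a: np.ndarray | ModelScore, scores_b: np.ndarray | ModelScore
                   ) -> dict[str, float]:
    """Paired one-sided t-test that model A scores lower (fits better) than B.

    Differences are b - a in NLML units, so a positive mean difference is an
    improvement of A over the reference B; reports the mean difference and
    its 95% CI in that convention.
    """
    a = scores_a.per_subject_score if isinstance(scores_a, ModelScore) else np.asarray(scores_a)
    b = scores_b.per_subject_score if isinstance(scores_b, ModelScore) else np.asarray(scores_b)
    if len(a) != len(b):
        raise ValueError("score vectors must cover the same subjects")
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 subjects for a paired comparison")
    d = b - a
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if np.allclose(d, 0) else np.inf * np.sign(d.mean())
    else:
        t = d.mean() / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    half = stats.t.ppf(0.975, df=n - 1) * sd / np.sqrt(n) if sd > 0 else 0.0
    return {
        "t_statistic": float(t),
        "one_sided_p": p,
        "mean_diff": float(d.mean()),
        "ci95_low": float(d.mean() - half),
        "ci95_high": float(d.mean() + half),
        "n": n,
    }
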
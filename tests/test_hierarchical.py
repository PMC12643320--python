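import numpy as np
import pytest
from scipy import integrate

from srtrace import hierarchical as hier
from srtrace import rt_model, synth
from srtrace.hierarchical import (
    FitOptions,
    GroupModel,
    MapObjective,
    compare_models,
    laplace_nlml,
    subject_map_fit,
    to_natural,
    to_unconstrained,
)
from srtrace.rt_model import MODELS


class TestTransforms:
    @pytest.mark.parametrize("name,value", [
        ("alpha_A", 0.15), ("gamma", 0.99), ("lam", 1e-4), ("shift_frac", 0.5),
        ("sigma", 0.2), ("mu0", 6.1), ("beta_A", -2.0),
    ])
    def test_round_trip_identity(self, name, value):
        assert abs(to_natural(name, to_unconstrained(name, value)) - value) < 1e-10

    def test_bounded_params_stay_in_range(self):
        for z in (-30.0, -1.0, 0.0, 1.0, 30.0):
            assert 0.0 <= to_natural("gamma", z) <= 1.0
            assert to_natural("sigma", min(z, 5.0)) > 0


class TestLaplace:
    def test_gaussian_gaussian_exact(self):
        """Laplace is exact for a quadratic objective; check against quadrature."""
        y = np.array([1.2, 0.8, 1.5, 0.9, 1.1])
        s, m = 0.5, 0.0  # likelihood sd, prior mean (prior sd 1)

        def neg_log_post(theta):
            nll = (len(y) * np.log(s) + 0.5 * len(y) * np.log(2 * np.pi)
                   + np.sum((y - theta) ** 2) / (2 * s**2))
            return nll + 0.5 * (theta - m) ** 2 + 0.5 * np.log(2 * np.pi)

        # MAP and curvature in closed form
        prec = len(y) / s**2 + 1.0
        theta_map = (y.sum() / s**2 + m) / prec
        nlml, pd = laplace_nlml(neg_log_post(theta_map), np.array([[prec]]), dim=1)
        assert pd
        exact, _ = integrate.quad(lambda t: np.exp(-neg_log_post(t)), -10, 10)
        assert abs(nlml - (-np.log(exact))) < 1e-8

    def test_unused_parameter_is_penalized(self):
        """Occam direction: an inert extra parameter cannot improve the NLML."""
        y = np.array([1.2, 0.8, 1.5, 0.9, 1.1])
        s = 0.5
        prec = len(y) / s**2 + 1.0
        theta_map = (y.sum() / s**2) / prec
        nll_map = (len(y) * np.log(s) + 0.5 * len(y) * np.log(2 * np.pi)
                   + np.sum((y - theta_map) ** 2) / (2 * s**2))
        f1 = nll_map + 0.5 * theta_map**2 + 0.5 * np.log(2 * np.pi)
        nlml1, _ = laplace_nlml(f1, np.array([[prec]]), dim=1)
        # second coordinate: zero likelihood influence, MAP at prior mean
        f2 = f1 + 0.5 * np.log(2 * np.pi)
        h2 = np.diag([prec, 1.0])
        nlml2, _ = laplace_nlml(f2, h2, dim=2)
        assert nlml2 >= nlml1 - 1e-12

    def test_dim_zero_degenerate(self):
        assert laplace_nlml(123.4, np.zeros((0, 0)), dim=0) == (123.4, True)


class TestCompareModels:
    def test_identical_scores(self):
        r = compare_models(np.arange(5.0), np.arange(5.0))
        assert r["t_statistic"] == 0.0 and r["one_sided_p"] == 0.5

    def test_hand_computed_example(self):
        r = compare_models(np.zeros(3), np.array([1.0, 2.0, 3.0]))
        assert np.isclose(r["t_statistic"], 2.0 / (1.0 / np.sqrt(3)))
        assert np.isclose(r["one_sided_p"], 0.0371, atol=5e-4)
        assert np.isclose(r["mean_diff"], 2.0)

    def test_constant_positive_difference_separates(self):
        rng = np.random.default_rng(0)
        b = 5.0 + 1e-6 * rng.standard_normal(30)
        r = compare_models(np.zeros(30), b)
        assert r["one_sided_p"] < 1e-10

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            compare_models(np.zeros(2), np.ones(2))


@pytest.fixture(scope="module")
def one_session(small_cohort):
    df, _ = small_cohort
    return rt_model.sessions_from_table(df)[0]


class TestMapObjective:
    def test_profile_equals_inner_minimum(self, one_session):
        """The ridge profile is the exact minimum of the full objective over betas."""
        model = MODELS["combined_sr_td"]
        opts = FitOptions(compute_laplace=False)
        group = hier.default_group_init(model, [one_session], opts)
        obj = MapObjective(model, [one_session], opts,
                           group.prior_mean(one_session.stage_covariate))
        phi = group.group_mean[obj.n_lin:]
        val, beta = obj.profile_value(phi)
        theta = np.concatenate([beta, phi])
        assert np.isclose(obj.full_value(theta), val)
        rng = np.random.default_rng(3)
        for _ in range(10):
            pert = theta.copy()
            pert[: obj.n_lin] += 0.1 * rng.standard_normal(obj.n_lin)
            assert obj.full_value(pert) >= val - 1e-9

    def test_gradient_zero_at_profile_optimum(self, one_session):
        model = MODELS["recency"]
        opts = FitOptions(compute_laplace=False)
        group = hier.default_group_init(model, [one_session], opts)
        obj = MapObjective(model, [one_session], opts,
                           group.prior_mean(one_session.stage_covariate))
        theta, val, ok = obj.fit(seed=0, n_restarts=1)
        h = 1e-5
        for i in range(obj.dim):
            e = np.zeros(obj.dim)
            e[i] = h
            g = (obj.full_value(theta + e) - obj.full_value(theta - e)) / (2 * h)
            assert abs(g) < 0.05  # stationarity of the MAP in every coordinate

    def test_shrinkage_toward_prior(self, one_session):
        model = MODELS["baseline"]
        opts = FitOptions(compute_laplace=False, include_targets=False)
        names = rt_model.param_names(model, include_targets=False)
        far = hier.default_group_init(model, [one_session], opts)
        mle_like = subject_map_fit(model, one_session, far, opts, seed=0)
        mu0_hat = mle_like.params_natural["mu0"]
        pulled_mean = far.group_mean.copy()
        i_mu0 = names.index("mu0")
        pulled_mean[i_mu0] = mu0_hat + 2.0  # prior far above the data optimum
        pulled = GroupModel(names=names, group_mean=pulled_mean,
                            stage_coef=np.zeros(len(names)))
        fit2 = subject_map_fit(model, one_session, pulled, opts, seed=0)
        assert mu0_hat < fit2.params_natural["mu0"] < mu0_hat + 2.0


class TestFlatData:
    def test_constant_rt_degenerate_fit(self):
        import pandas as pd

        n = 700
        df = pd.DataFrame({
            "subject": "s1", "graphset": "g1", "stage": 1,
            "trial": np.arange(1, n + 1), "node": (np.arange(n) % 15) + 1,
            "target": (np.arange(n) % 15) + 1,
            "rt_ms": 600.0, "correct": True,
        })
        s = rt_model.sessions_from_table(rt_model.preprocess(df))[0]
        model = MODELS["baseline"]
        opts = FitOptions(compute_laplace=False, include_targets=False)
        group = hier.default_group_init(model, [s], opts)
        fit = subject_map_fit(model, s, group, opts, seed=0)
        p = fit.params_natural
        assert p["sigma"] < 0.05
        assert abs(p["mu0"] - np.log(600.0 - p["shift_frac"] * 600.0)) < 0.1


class TestEM:
    def test_mstep_mean_is_average_without_covariate(self, small_cohort):
        df, _ = small_cohort
        sessions = rt_model.sessions_from_table(df)
        sessions = [s for s in sessions if s.stage == 1][:4]
        model = MODELS["recency"]
        opts = FitOptions(n_restarts=1, em_max_iter=1, compute_laplace=False)
        res = hier.em_fit(model, sessions, opts)
        thetas = np.array([f.theta_map for f in res.fits])
        assert np.allclose(res.group.stage_coef, 0.0)
        # after the final E-step the recorded MAPs sit under the final prior;
        # re-run one E-step and check the M-step average identity directly
        refits = [subject_map_fit(model, s, res.group, opts, seed=0,
                                  x0=f.theta_map, n_restarts=1)
                  for s, f in zip(sessions, res.fits)]
        avg = np.mean([f.theta_map for f in refits], axis=0)
        design = np.ones((len(sessions), 1))
        lstsq_mean = np.linalg.lstsq(design, np.array([f.theta_map for f in refits]),
                                     rcond=None)[0][0]
        assert np.allclose(avg, lstsq_mean)

    def test_requires_two_subjects(self, one_session):
        with pytest.raises(ValueError):
            hier.em_fit(MODELS["baseline"], [one_session], FitOptions())

    def test_em_reduces_total_evidence_proxy(self, small_cohort):
        """Total approximate NLML is (weakly) decreasing over EM iterations."""
        df, _ = small_cohort
        sessions = rt_model.sessions_from_table(df)[:5]
        model = MODELS["recency"]
        opts = FitOptions(n_restarts=1, compute_laplace=False)
        group = hier.default_group_init(model, sessions, opts)
        totals = []
        warm = [None] * len(sessions)
        for it in range(4):
            nlmls = []
            thetas = []
            for i, s in enumerate(sessions):
                obj = MapObjective(model, [s], opts, group.prior_mean(s.stage_covariate))
                theta, value, _ = obj.fit(seed=0, x0=warm[i], n_restarts=1)
                warm[i] = theta
                thetas.append(theta)
                nlml, _ = laplace_nlml(value, obj.hessian(theta), obj.dim)
                nlmls.append(nlml)
            totals.append(sum(nlmls))
            group = GroupModel(names=group.names,
                               group_mean=np.mean(thetas, axis=0),
                               stage_coef=np.zeros(len(group.names)))
        drops = [totals[i + 1] - totals[i] <= 1e-6 for i in range(len(totals) - 1)]
        assert sum(drops) >= len(drops) - 1  # Laplace can break exactness once


class TestCoverage:
    def test_map_within_three_posterior_sd(self, modular):
        """MAP +- 3 posterior SDs covers the generating parameters."""
        model = MODELS["sr_td"]
        opts = FitOptions(n_restarts=1, compute_laplace=False, include_targets=False)
        names = rt_model.param_names(model, include_targets=False)
        m0 = np.array([to_unconstrained(n, v) for n, v in zip(names, [
            6.0, -0.1, -2.0, 0.02, -0.02, 0.15, 0.8, 0.7, 0.5, 0.2])])
        group = GroupModel(names=names, group_mean=m0, stage_coef=np.zeros(len(names)))
        rng = np.random.default_rng(21)
        n_rep, covered = 25, 0
        for rep in range(n_rep):
            theta_true = m0 + 0.5 * rng.standard_normal(len(m0))
            params = {n: to_natural(n, v) for n, v in zip(names, theta_true)}
            shift_ms = 250.0
            agent = synth.AgentSpec(model="sr_td", params=params, shift_ms=shift_ms,
                                    error_rate=0.0, fastguess_rate=0.0)
            df = rt_model.preprocess(
                synth.simulate_subject(agent, modular, 1500, 1, seed=500 + rep))
            s = rt_model.sessions_from_table(df)[0]
            theta_true[names.index("shift_frac")] = to_unconstrained(
                "shift_frac", min(shift_ms / s.min_rt, 0.999))
            fit = subject_map_fit(model, s, group, opts, seed=rep)
            obj = MapObjective(model, [s], opts, group.prior_mean(s.stage_covariate))
            h = obj.hessian(fit.theta_map)
            sd = np.sqrt(np.diag(np.linalg.inv(h)))
            # shift_frac is excluded: its truth sits against the rt > shift
            # support boundary, where Gaussian (Laplace) posterior SDs are
            # unreliable -- the classic shifted-lognormal threshold pathology
            regular = [i for i, n in enumerate(names) if n != "shift_frac"]
            covered += np.all(
                np.abs(fit.theta_map - theta_true)[regular] <= 3 * sd[regular])
        assert covered / n_rep >= 0.9
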
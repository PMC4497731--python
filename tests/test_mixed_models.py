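"""Mixed-model ML fitting against independent oracles.

The profiled Gram-matrix likelihood is checked against (a) closed
degenerate forms (OLS, plain logistic), (b) a dense-covariance
full-parameter numerical maximization built here from first principles,
(c) statsmodels, and (d) a scipy quadrature evaluation of the binomial
marginal likelihood.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, optimize, special, stats

from boargrowth.mixed_models import (
    LMMWorkspace,
    ModelSpec,
    aicc,
    fit_glmm_binomial,
    fit_lm,
    fit_lmm,
)


def simulate_lmm(rng, n_groups=8, per_group=6, beta=(0.5, -1.2), tau=0.4, sigma=0.7):
    g = np.repeat([f"g{i:02d}" for i in range(n_groups)], per_group)
    x = rng.normal(size=len(g))
    u = dict(zip(sorted(set(g)), rng.normal(0, tau, n_groups)))
    y = beta[0] + beta[1] * x + np.array([u[k] for k in g]) + rng.normal(0, sigma, len(g))
    return pd.DataFrame(dict(y=y, x=x, g=g))


class TestAicc:
    def test_direct_formula(self):
        assert aicc(-100.0, 3, 100) == pytest.approx(206.0 + 24 / 96)

    def test_large_n_limit_is_aic(self):
        assert aicc(-50.0, 4, 10**8) == pytest.approx(108.0, abs=1e-5)

    def test_k_zero(self):
        assert aicc(-10.0, 0, 5) == pytest.approx(20.0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestLMMDegenerate:
    def test_zero_group_variance_matches_ols(self, rng):
        # construct data with exactly zero between-group variation (both in
        # the predictor and the noise) so the boundary fit tau-hat = 0 is
        # guaranteed and the OLS equivalence is exact, not approximate
        g = np.repeat([f"g{i:02d}" for i in range(8)], 6)
        x = rng.normal(size=len(g))
        e = rng.normal(0, 0.7, len(g))
        df = pd.DataFrame(dict(x=x, e=e, g=g))
        df["x"] -= df.groupby("g")["x"].transform("mean")
        df["e"] -= df.groupby("g")["e"].transform("mean")
        df["y"] = 0.5 - 1.2 * df["x"] + df["e"]
        lmm = fit_lmm(df, ModelSpec("y", ("x",), ("g",)))
        sm = pytest.importorskip("statsmodels.api")
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert lmm.beta["x"] == pytest.approx(ols.params.iloc[1], abs=1e-6)
        assert lmm.beta["(Intercept)"] == pytest.approx(ols.params.iloc[0], abs=1e-6)
        assert lmm.tau2["g"] < 1e-4

    def test_intercept_only_grand_mean(self, rng):
        df = simulate_lmm(rng, tau=0.0)
        m = fit_lmm(df, ModelSpec("y", (), ("g",)))
        assert m.beta["(Intercept)"] == pytest.approx(df["y"].mean(), abs=1e-5)


class TestLMMOracle:
    def dense_ml(self, df, terms, groups):
        """Independent oracle: dense covariance, GLS beta, numerical
        maximization directly over the variance components."""
        X = np.column_stack([np.ones(len(df))] + [df[t].to_numpy() for t in terms])
        y = df["y"].to_numpy()
        Zs = []
        for g in groups:
            codes, _ = pd.factorize(df[g], sort=True)
            Z = np.zeros((len(df), codes.max() + 1))
            Z[np.arange(len(df)), codes] = 1
            Zs.append(Z)

        def nll(params):
            log_s2 = params[0]
            taus = np.exp(params[1:])
            V = np.exp(log_s2) * np.eye(len(y))
            for t2, Z in zip(taus, Zs):
                V += t2 * Z @ Z.T
            sign, logdet = np.linalg.slogdet(V)
            Vi = np.linalg.inv(V)
            b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ b
            return 0.5 * (logdet + r @ Vi @ r + len(y) * np.log(2 * np.pi))

        best = np.inf
        for start in ([np.log(0.5)] + [np.log(0.1)] * len(groups),
                      [0.0] + [np.log(0.5)] * len(groups)):
            res = optimize.minimize(nll, np.array(start), method="Nelder-Mead",
                                    options=dict(xatol=1e-10, fatol=1e-10, maxiter=4000))
            best = min(best, res.fun)
        return -best

    def test_profiled_matches_dense_full_maximization(self, rng):
        df = simulate_lmm(rng, n_groups=7, per_group=7)
        m = fit_lmm(df, ModelSpec("y", ("x",), ("g",)))
        oracle = self.dense_ml(df, ("x",), ("g",))
        assert m.loglik == pytest.approx(oracle, abs=1e-4)

    def test_profiled_matches_dense_two_factors(self, rng):
        df = simulate_lmm(rng, n_groups=9, per_group=5)
        df["outer"] = ["a" if g in ("g0", "g1", "g2", "g3") else "b" for g in df["g"]]
        m = fit_lmm(df, ModelSpec("y", ("x",), ("outer", "g")))
        oracle = self.dense_ml(df, ("x",), ("outer", "g"))
        assert m.loglik == pytest.approx(oracle, abs=1e-4)

    def test_balanced_oneway_closed_form(self, rng):
        # balanced one-way layout: ML variance components have closed
        # ANOVA-type forms when interior
        a, m_per = 12, 8
        tau, sigma = 0.9, 0.5
        g = np.repeat([f"g{i:02d}" for i in range(a)], m_per)
        y = np.repeat(rng.normal(0, tau, a), m_per) + rng.normal(0, sigma, a * m_per)
        df = pd.DataFrame(dict(y=y, g=g))
        fit = fit_lmm(df, ModelSpec("y", (), ("g",)))
        gm = df.groupby("g")["y"].mean().to_numpy()
        sse = float(((y - np.repeat(gm, m_per)) ** 2).sum())
        s2_hat = sse / (a * (m_per - 1))
        ssa = float(m_per * ((gm - y.mean()) ** 2).sum())
        tau2_hat = max(ssa / a / m_per - s2_hat / m_per, 0.0)  # ML between-variance
        assert fit.sigma2 == pytest.approx(s2_hat, rel=1e-3)
        assert fit.tau2["g"] == pytest.approx(tau2_hat, rel=2e-2)

    def test_statsmodels_mixedlm_cross_check(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        df = simulate_lmm(rng, n_groups=10, per_group=8, tau=0.6)
        m = fit_lmm(df, ModelSpec("y", ("x",), ("g",)))
        sm_fit = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=False)
        assert m.beta["x"] == pytest.approx(sm_fit.params["x"], abs=1e-4)
        assert m.loglik == pytest.approx(sm_fit.llf, abs=1e-4)

    def test_adding_terms_never_decreases_loglik(self, rng):
        df = simulate_lmm(rng, n_groups=8, per_group=8)
        df["x2"] = rng.normal(size=len(df))
        ws = LMMWorkspace(df, "y", ("x", "x2"), ("g",))
        ll0 = ws.fit(()).loglik
        ll1 = ws.fit(("x",)).loglik
        ll2 = ws.fit(("x", "x2")).loglik
        assert ll1 >= ll0 - 1e-6 and ll2 >= ll1 - 1e-6

    def test_rank_deficiency_named(self, rng):
        df = simulate_lmm(rng)
        df["x_dup"] = df["x"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_lmm(df, ModelSpec("y", ("x", "x_dup"), ("g",)))


class TestLM:
    def test_matches_statsmodels_ols(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        df = pd.DataFrame(dict(y=rng.normal(size=30), x=rng.normal(size=30)))
        m = fit_lm(df, ModelSpec("y", ("x",)))
        ols = sm.OLS(df["y"], sm.add_constant(df["x"])).fit()
        assert m.beta["x"] == pytest.approx(ols.params.iloc[1], rel=1e-9)
        assert m.se["x"] == pytest.approx(ols.bse.iloc[1], rel=1e-6)

    def test_constant_response_zero_slopes(self, rng):
        df = pd.DataFrame(dict(y=np.full(20, 3.0), x=rng.normal(size=20)))
        m = fit_lm(df, ModelSpec("y", ("x",)))
        assert m.beta["x"] == pytest.approx(0.0, abs=1e-10)


def simulate_glmm(rng, n_groups=10, per_group=25, beta=(-0.3, 0.8), tau=0.8):
    g = np.repeat([f"g{i}" for i in range(n_groups)], per_group)
    x = rng.normal(size=len(g))
    u = np.repeat(rng.normal(0, tau, n_groups), per_group)
    p = special.expit(beta[0] + beta[1] * x + u)
    return pd.DataFrame(dict(y=(rng.uniform(size=len(g)) < p).astype(float), x=x, g=g))


class TestGLMM:
    def test_zero_variance_matches_plain_logistic(self):
        sm = pytest.importorskip("statsmodels.api")
        # fixed draw whose ML group variance lies on the tau = 0 boundary,
        # where the mixed fit must coincide with plain logistic regression
        df = simulate_glmm(np.random.default_rng(0), tau=0.0)
        m = fit_glmm_binomial(df, ModelSpec("y", ("x",), ("g",), "binomial"))
        logit = sm.Logit(df["y"], sm.add_constant(df["x"])).fit(disp=0)
        assert m.beta["x"] == pytest.approx(logit.params.iloc[1], abs=1e-4)
        assert m.beta["(Intercept)"] == pytest.approx(logit.params.iloc[0], abs=1e-4)

    def test_null_trend_usually_nonsignificant(self):
        flags = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            df = simulate_glmm(r, beta=(-0.2, 0.0), tau=0.5)
            m = fit_glmm_binomial(df, ModelSpec("y", ("x",), ("g",), "binomial"))
            flags.append(abs(m.z("x")) < 2)
        assert sum(flags) >= 4

    def test_quadrature_against_scipy_integration(self, rng):
        """GH-15 marginal log-likelihood equals brute-force quad at fixed params."""
        df = simulate_glmm(rng, n_groups=4, per_group=15)
        beta = np.array([-0.2, 0.6])
        tau = 0.7
        X = np.column_stack([np.ones(len(df)), df["x"]])
        eta = X @ beta
        total = 0.0
        for gname, sub in df.groupby("g"):
            idx = sub.index.to_numpy()

            def integrand(b, idx=idx):
                e = eta[idx] + b
                ll = np.sum(df["y"].to_numpy()[idx] * e - np.logaddexp(0, e))
                return np.exp(ll) * stats.norm.pdf(b, 0, tau)

            val, _ = integrate.quad(integrand, -8 * tau, 8 * tau, limit=200)
            total += np.log(val)

        from boargrowth.mixed_models import glmm_marginal_loglik

        got = glmm_marginal_loglik(
            df, ModelSpec("y", ("x",), ("g",), "binomial"), beta, tau**2, n_nodes=15)
        assert got == pytest.approx(total, abs=1e-6)

    def test_loglik_improves_with_nodes(self, rng):
        """Laplace (1 node) and GH-15 agree to ~1e-2 and the fit is stable."""
        df = simulate_glmm(rng, n_groups=8, per_group=20)
        m1 = fit_glmm_binomial(df, ModelSpec("y", ("x",), ("g",), "binomial"), n_nodes=1)
        m15 = fit_glmm_binomial(df, ModelSpec("y", ("x",), ("g",), "binomial"), n_nodes=15)
        m31 = fit_glmm_binomial(df, ModelSpec("y", ("x",), ("g",), "binomial"), n_nodes=31)
        assert m15.beta["x"] == pytest.approx(m1.beta["x"], abs=0.05)
        assert m31.loglik == pytest.approx(m15.loglik, abs=1e-3)

    def test_trend_recovery_within_2se(self):
        hits = 0
        for seed in range(8):
            r = np.random.default_rng(1000 + seed)
            df = simulate_glmm(r, beta=(-0.5, 0.6), tau=0.5)
            m = fit_glmm_binomial(df, ModelSpec("y", ("x",), ("g",), "binomial"))
            hits += abs(m.beta["x"] - 0.6) <= 2 * m.se["x"]
        assert hits >= 6
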
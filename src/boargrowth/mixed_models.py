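"""Maximum-likelihood model fitting.

Three families back the pipeline:

* :func:`fit_lmm` — Gaussian linear mixed models with any number of
  random-intercept factors (nested factors are expressed by giving the
  inner factor labels unique within the outer one).  The likelihood is
  profiled: for fixed variance ratios ``gamma_g = tau_g^2 / sigma^2``
  the fixed effects and the residual variance have closed GLS/ML forms,
  so only the ratios are optimized numerically (on the log scale,
  derivative-free, fixed start 0.1).  All quantities are evaluated from
  cached cross-product (Gram) matrices via the Woodbury identity, so a
  likelihood evaluation costs O(q^3) in the number of random levels q,
  independent of n — which is what makes fitting thousands of candidate
  models feasible.
* :func:`fit_glmm_binomial` — random-intercept logistic regression,
  marginal likelihood by adaptive Gauss-Hermite quadrature (default 15
  nodes; 1 node is the Laplace approximation).
* :func:`fit_lm` — ordinary least squares through the same bookkeeping.

Everything is ML, not REML: AICc comparisons across fixed-effect
structures require a likelihood that is comparable across those
structures.  The parameter count k includes all fixed effects, all
variance components and (Gaussian) the residual variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

INTERCEPT = "(Intercept)"

_GAMMA_STARTS = (0.1, 0.001, 1.0)  # variance-ratio starting points (restarts)
_XTOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """Response, ordered fixed terms and random-intercept grouping columns.

    Interactions are written ``"a:b"`` and are formed as the product of
    the named (already standardized) columns.  The intercept is always
    included and not listed.  ``random_groups`` is ordered outer to
    inner; labels of an inner nested factor must be unique across outer
    levels (e.g. region labels carrying their country prefix).
    """

    response: str
    fixed_terms: tuple[str, ...]
    random_groups: tuple[str, ...] = ()
    family: str = "gaussian"

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "fixed_terms", tuple(self.fixed_terms))
        object.__setattr__(self, "random_groups", tuple(self.random_groups))


@dataclass
class FittedModel:
    """A fitted model: estimates, SEs, variance components and AICc."""

    spec: ModelSpec
    beta: dict[str, float]
    se: dict[str, float]
    vcov: np.ndarray
    sigma2: float | None
    tau2: dict[str, float]
    loglik: float
    k: int
    n: int
    aicc: float
    converged: bool
    residuals: np.ndarray
    message: str = ""

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.beta)

    def z(self, term: str) -> float:
        return self.beta[term] / self.se[term]

    def wald_p(self, term: str) -> float:
        """Two-sided p-value from the normal approximation z = beta/se."""
        b, s = self.beta[term], self.se[term]
        if abs(b) < 1e-8 and s < 1e-8:  # exact-fit float dust is null
            return 1.0
        return float(2.0 * stats.norm.sf(abs(self.z(term))))

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.beta:
            rows.append(dict(term=t, estimate=self.beta[t], se=self.se[t],
                             z=self.z(t), p=self.wald_p(t)))
        return pd.DataFrame(rows).set_index("term")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def design_matrix(data: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + named columns; ``a:b`` terms are products of columns."""
    n = len(data)
    cols = [np.ones(n)]
    names = [INTERCEPT]
    for t in terms:
        if ":" in t:
            parts = t.split(":")
            x = np.ones(n)
            for p in parts:
                x = x * data[p].to_numpy(float)
        else:
            x = data[t].to_numpy(float)
        cols.append(x)
        names.append(t)
    return np.column_stack(cols), names


def _group_indicators(data: pd.DataFrame, groups: Sequence[str]):
    """Stacked 0/1 indicator matrix for each grouping factor, with slices."""
    blocks, slices, levels = [], [], {}
    start = 0
    for g in groups:
        codes, uniq = pd.factorize(data[g], sort=True)
        q = len(uniq)
        Z = np.zeros((len(data), q))
        Z[np.arange(len(data)), codes] = 1.0
        blocks.append(Z)
        slices.append(slice(start, start + q))
        levels[g] = list(uniq)
        start += q
    Z = np.hstack(blocks) if blocks else np.zeros((len(data), 0))
    return Z, slices, levels


class LMMWorkspace:
    """Cached design and Gram matrices for fitting many nested Gaussian models.

    Build once from the maximal fixed-term set; every candidate model is
    then fitted from sub-blocks of the cached cross-products.
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 all_terms: Sequence[str], random_groups: Sequence[str]):
        self.response = response
        self.all_terms = tuple(all_terms)
        self.random_groups = tuple(random_groups)
        self.n = len(data)
        self.X, self.colnames = design_matrix(data, all_terms)
        self.y = data[response].to_numpy(float)
        self.Z, self.group_slices, self.group_levels = _group_indicators(data, random_groups)
        self.q = self.Z.shape[1]
        C = np.column_stack([self.X, self.y])
        self.Czz = self.Z.T @ self.Z
        self.Czc = self.Z.T @ C
        self.Ccc = C.T @ C

    # -- profiled quantities -------------------------------------------------

    def _gamma_vector(self, gammas: np.ndarray) -> np.ndarray:
        d = np.empty(self.q)
        for g, sl in zip(gammas, self.group_slices):
            d[sl] = g
        return d

    def _profile(self, cols: np.ndarray, gammas: np.ndarray):
        """GLS fit and profiled ML log-likelihood at fixed variance ratios."""
        n = self.n
        idx = np.append(cols, self.X.shape[1])  # fixed columns + response
        if self.q:
            sd = np.sqrt(self._gamma_vector(gammas))
            M = np.eye(self.q) + (sd[:, None] * self.Czz) * sd[None, :]
            L = np.linalg.cholesky(M)
            B = np.linalg.solve(L, sd[:, None] * self.Czc[:, idx])
            S = self.Ccc[np.ix_(idx, idx)] - B.T @ B
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        else:
            S = self.Ccc[np.ix_(idx, idx)]
            logdet = 0.0
        Sxx, Sxy, Syy = S[:-1, :-1], S[:-1, -1], S[-1, -1]
        try:
            beta = np.linalg.solve(Sxx, Sxy)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "rank-deficient fixed-effect design; collinear terms among "
                + ", ".join(np.asarray(self.colnames)[cols])
            )
        rss = float(Syy - Sxy @ beta)
        rss = max(rss, 1e-300)
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
        return ll, beta, sigma2, Sxx

    def fit(self, terms: Sequence[str]) -> FittedModel:
        """Profiled-ML fit of the model with the given fixed-term subset."""
        terms = tuple(terms)
        unknown = [t for t in terms if t not in self.all_terms]
        if unknown:
            raise ValueError(f"terms not in workspace: {unknown}")
        cols = np.array([0] + [self.colnames.index(t) for t in terms])
        nfac = len(self.random_groups)
        gram = self.Ccc[np.ix_(cols, cols)]
        if np.linalg.matrix_rank(gram, hermitian=True) < len(cols):
            raise np.linalg.LinAlgError(
                "rank-deficient fixed-effect design; collinear terms among "
                + ", ".join(np.asarray(self.colnames)[cols]))

        converged = True
        message = ""
        if nfac == 0:
            gam_hat = np.empty(0)
            ll, beta, sigma2, Sxx = self._profile(cols, gam_hat)
        else:
            def nll(theta):
                try:
                    return -self._profile(cols, np.exp(theta))[0]
                except np.linalg.LinAlgError:
                    return np.inf

            best = None
            for g0 in _GAMMA_STARTS:
                res = optimize.minimize(
                    nll, np.full(nfac, np.log(g0)), method="Nelder-Mead",
                    options=dict(xatol=_XTOL, fatol=_XTOL, maxiter=2000))
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
                if best.success and g0 == _GAMMA_STARTS[0]:
                    break
            gam_hat = np.exp(best.x)
            # boundary: variance components estimated at (numerical) zero
            gam_hat[gam_hat < 1e-8] = 0.0
            converged = bool(best.success) or best.fun < np.inf
            if not best.success:
                message = f"optimizer: {best.message}"
            ll, beta, sigma2, Sxx = self._profile(cols, gam_hat)

        vcov = sigma2 * np.linalg.inv(Sxx)
        se = np.sqrt(np.diag(vcov))
        names = [self.colnames[c] for c in cols]
        k = len(cols) + nfac + 1
        resid = self._conditional_residuals(cols, beta, gam_hat)
        return FittedModel(
            spec=ModelSpec(self.response, terms, self.random_groups, "gaussian"),
            beta=dict(zip(names, beta)), se=dict(zip(names, se)), vcov=vcov,
            sigma2=sigma2,
            tau2={g: float(gam * sigma2) for g, gam in zip(self.random_groups, gam_hat)},
            loglik=float(ll), k=k, n=self.n, aicc=aicc(float(ll), k, self.n),
            converged=converged, residuals=resid, message=message,
        )

    def _conditional_residuals(self, cols, beta, gammas) -> np.ndarray:
        r = self.y - self.X[:, cols] @ beta
        if self.q == 0 or len(gammas) == 0 or not np.any(gammas):
            return r
        d = self._gamma_vector(gammas)
        sd = np.sqrt(d)
        M = np.eye(self.q) + (sd[:, None] * self.Czz) * sd[None, :]
        zr = self.Z.T @ r
        zvr = zr - self.Czz @ (sd * np.linalg.solve(M, sd * zr))
        b = d * zvr  # BLUPs of the random intercepts
        return r - self.Z @ b


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """ML fit of a Gaussian linear mixed model with random intercepts."""
    ws = LMMWorkspace(data, spec.response, spec.fixed_terms, spec.random_groups)
    if ws.n <= len(spec.fixed_terms) + len(spec.random_groups) + 2:
        raise ValueError("too few observations for the requested model")
    return ws.fit(spec.fixed_terms)


def fit_lm(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Ordinary least squares (no random terms), ML log-likelihood and AICc.

    Standard errors use the unbiased residual variance (denominator
    n - p, as in conventional regression output); the log-likelihood and
    AICc use the ML variance so that model comparison is likelihood-based.
    """
    if spec.random_groups:
        raise ValueError("fit_lm takes no random groups; use fit_lmm")
    ws = LMMWorkspace(data, spec.response, spec.fixed_terms, ())
    m = ws.fit(spec.fixed_terms)
    p = len(m.beta)
    if ws.n < p + 2:
        raise ValueError("too few observations")
    scale = ws.n / (ws.n - p)
    m.vcov = m.vcov * scale
    m.se = {t: s * np.sqrt(scale) for t, s in m.se.items()}
    return m


# ---------------------------------------------------------------------------
# binomial random-intercept models


def _expit(x):
    return special.expit(x)


def glmm_marginal_loglik(data: pd.DataFrame, spec: ModelSpec, beta, tau2: float,
                         n_nodes: int = 15) -> float:
    """Marginal log-likelihood of a random-intercept logistic model at
    fixed parameters, by the same adaptive quadrature the fitter uses."""
    X, _ = design_matrix(data, spec.fixed_terms)
    y = data[spec.response].to_numpy(float)
    codes, _ = pd.factorize(data[spec.random_groups[0]], sort=True)
    groups = [np.flatnonzero(codes == g) for g in range(codes.max() + 1)]
    t_nodes, w_nodes = np.polynomial.hermite.hermgauss(n_nodes)
    eta = X @ np.asarray(beta, float)
    log_tau = 0.5 * np.log(tau2)
    total = 0.0
    for idx in groups:
        total += _group_marginal(eta[idx], y[idx], log_tau, t_nodes, w_nodes)[0]
    return float(total)


def _group_marginal(eta_g, y_g, log_tau, t_nodes, w_nodes):
    """Adaptive GH integral of one group's likelihood over its intercept."""
    tau2 = np.exp(2.0 * log_tau)
    b = 0.0
    for _ in range(50):
        mu = _expit(eta_g + b)
        g1 = float(np.sum(y_g - mu)) - b / tau2
        g2 = -float(np.sum(mu * (1 - mu))) - 1.0 / tau2
        step = g1 / g2
        b -= step
        if abs(step) < 1e-10:
            break
    h = float(np.sum(_expit(eta_g + b) * (1 - _expit(eta_g + b)))) + 1.0 / tau2
    bb = b + np.sqrt(2.0 / h) * t_nodes
    eta = eta_g[:, None] + bb[None, :]
    f = (np.sum(y_g[:, None] * eta - np.logaddexp(0.0, eta), axis=0)
         - bb**2 / (2.0 * tau2) - 0.5 * np.log(2.0 * np.pi * tau2))
    logint = special.logsumexp(np.log(w_nodes) + t_nodes**2 + f)
    return logint + 0.5 * np.log(2.0 / h), b


def fit_glmm_binomial(data: pd.DataFrame, spec: ModelSpec, n_nodes: int = 15) -> FittedModel:
    """Random-intercept logistic regression by adaptive Gauss-Hermite quadrature.

    One random grouping level; the marginal likelihood integrates the
    group intercepts over N(0, tau^2) with ``n_nodes`` quadrature nodes
    centred and scaled at each group's conditional mode (1 node =
    Laplace approximation).
    """
    if spec.family != "binomial":
        raise ValueError("spec.family must be 'binomial'")
    if len(spec.random_groups) != 1:
        raise ValueError("binomial mixed model supports exactly one random grouping level")
    X, names = design_matrix(data, spec.fixed_terms)
    y = data[spec.response].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be 0/1")
    codes, levels = pd.factorize(data[spec.random_groups[0]], sort=True)
    n, p = X.shape
    groups = [np.flatnonzero(codes == g) for g in range(len(levels))]
    t_nodes, w_nodes = np.polynomial.hermite.hermgauss(n_nodes)

    def nll(params):
        beta, log_tau = params[:p], params[p]
        if log_tau > 5 or np.abs(beta).max() > 50:
            return 1e10
        eta = X @ beta
        total = 0.0
        for idx in groups:
            total += _group_marginal(eta[idx], y[idx], log_tau, t_nodes, w_nodes)[0]
        return -total

    beta0 = _logistic_start(X, y)
    x0 = np.append(beta0, np.log(0.5))
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options=dict(xatol=1e-7, fatol=1e-9, maxiter=5000, maxfev=10000))
    beta_hat, log_tau_hat = res.x[:p], res.x[p]
    tau2_hat = float(np.exp(2.0 * log_tau_hat))
    ll = -res.fun
    converged = bool(res.success) and np.abs(beta_hat).max() < 40
    message = "" if converged else f"possible separation or non-convergence: {res.message}"

    # observed-information SEs for the fixed effects by numerical Hessian;
    # at the tau -> 0 boundary the Hessian is singular in log-tau, so fall
    # back to the plain-logistic Fisher information
    if tau2_hat < 1e-6:
        mu = _expit(X @ beta_hat)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        vcov = np.linalg.inv((X * w[:, None]).T @ X)
    else:
        vcov = _numeric_vcov(nll, res.x, p)
    se = np.sqrt(np.maximum(np.diag(vcov), 0.0))

    eta = X @ beta_hat
    bhat = np.zeros(n)
    for idx in groups:
        _, b = _group_marginal(eta[idx], y[idx], log_tau_hat, t_nodes, w_nodes)
        bhat[idx] = b
    resid = y - _expit(eta + bhat)

    k = p + 1  # fixed effects + one variance component
    return FittedModel(
        spec=spec, beta=dict(zip(names, beta_hat)), se=dict(zip(names, se)),
        vcov=vcov, sigma2=None, tau2={spec.random_groups[0]: tau2_hat},
        loglik=float(ll), k=k, n=n, aicc=aicc(float(ll), k, n),
        converged=converged, residuals=resid, message=message,
    )


def _logistic_start(X, y, n_iter: int = 25) -> np.ndarray:
    """Plain logistic regression by damped IRLS, used as a starting point."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        mu = _expit(X @ beta)
        w = np.clip(mu * (1 - mu), 1e-6, None)
        try:
            step = np.linalg.solve((X * w[:, None]).T @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -5, 5)
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            break
    return np.clip(beta, -10, 10)


def _numeric_vcov(nll, x, p, h: float = 1e-4) -> np.ndarray:
    """Fixed-effect covariance from a central-difference Hessian of the NLL."""
    m = len(x)
    H = np.zeros((m, m))
    f0 = nll(x)
    for i in range(m):
        for j in range(i, m):
            xi = x.copy(); xi[i] += h; xi[j] += h; fpp = nll(xi)
            xi = x.copy(); xi[i] += h; xi[j] -= h; fpm = nll(xi)
            xi = x.copy(); xi[i] -= h; xi[j] += h; fmp = nll(xi)
            xi = x.copy(); xi[i] -= h; xi[j] -= h; fmm = nll(xi)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
    try:
        V = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        V = np.full((m, m), np.nan)
    if np.any(np.diag(V)[:p] < 0):
        warnings.warn("non-positive-definite Hessian; SEs unreliable", stacklevel=2)
    return V[:p, :p]
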
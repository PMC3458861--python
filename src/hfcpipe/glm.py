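"""Count and richness regressions: Gaussian and negative-binomial GLMs.

Parasite counts are overdispersed, so abundance responses use the NB2
negative binomial with a log link (Var = mu + mu^2/theta; theta -> inf
recovers the Poisson).  Endoparasite species richness is modeled Gaussian.
Both are exposed as scikit-learn-style estimators (``fit(X, y)``, fitted
attributes with trailing underscores, ``get_params``/``set_params``) built
around a shared :class:`FitResult` record that the model-selection layer
consumes.

The parameter count ``k`` of every fit includes the dispersion parameter
(theta for the negative binomial, sigma^2 for the Gaussian) in addition to
the regression coefficients — the convention under which AICc comparisons
between the two stages are coherent.

AICc = -2 logL + 2k + 2k(k+1)/(n-k-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .design import DesignEncoder, ModelSpec

__all__ = [
    "FitResult",
    "GaussianGLM",
    "NegativeBinomialGLM",
    "fit_gaussian",
    "fit_negbin",
    "aicc",
    "nb_loglik",
    "nb_deviance",
]

THETA_BOUNDS = (1e-3, 1e6)


@dataclass
class FitResult:
    """One fitted model, in the form the selection machinery needs."""

    label: str
    family: str
    params: pd.Series
    bse: pd.Series
    llf: float
    k: int
    nobs: int
    deviance: float
    df_resid: int
    dispersion: float  # theta (negbin) or sigma^2 (gaussian)
    converged: bool
    theta_boundary: bool = False
    spec: ModelSpec | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_coef(self) -> int:
        return len(self.params)


def aicc(fit: FitResult, n: int | None = None) -> float:
    """Small-sample-corrected AIC for a fit; undefined unless n > k + 1."""
    n = fit.nobs if n is None else n
    k = fit.k
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * fit.llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """Full NB2 log-likelihood (theta is the dispersion, Var = mu + mu^2/theta)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    """NB2 deviance at fixed theta: 2*(loglik saturated - loglik at mu)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(term1 - term2))


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns involved via QR pivoting for a useful message
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


class _SpecEstimator(BaseEstimator, RegressorMixin):
    """Shared scaffolding: encode the spec's design from a covariate frame."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec

    def _design(self, X: pd.DataFrame, refit: bool) -> pd.DataFrame:
        if refit:
            self.encoder_ = DesignEncoder(self.spec).fit(X)
        return self.encoder_.transform(X)

    @property
    def result_(self) -> FitResult:
        return self._result


class GaussianGLM(_SpecEstimator):
    """Ordinary least squares with Gaussian ML log-likelihood bookkeeping.

    ``k`` counts the coefficients plus sigma^2; logL uses the ML variance
    estimate sigma^2 = RSS/n, i.e. -n/2 (log(2 pi RSS/n) + 1).
    """

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            y = X[self.spec.response]
        y = np.asarray(y, dtype=float)
        D = self._design(X, refit=True)
        if len(y) <= D.shape[1]:
            raise ValueError(f"n={len(y)} too small for {D.shape[1]} columns")
        _check_rank(D)
        res = sm.OLS(y, D).fit()
        n = len(y)
        rss = float(res.ssr)
        k = D.shape[1] + 1
        self._result = FitResult(
            label=self.spec.label,
            family="gaussian",
            params=res.params,
            bse=res.bse,
            llf=float(res.llf),
            k=k,
            nobs=n,
            deviance=rss,
            df_resid=n - D.shape[1],
            dispersion=rss / n,
            converged=True,
            spec=self.spec,
            extra={"rss": rss},
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        D = self._design(X, refit=False)
        return D.to_numpy() @ self._result.params.to_numpy()


class NegativeBinomialGLM(_SpecEstimator):
    """NB2 log-link GLM with theta estimated by profile maximum likelihood.

    Alternates an IRLS step for the coefficients at fixed theta with a
    bounded 1-D likelihood maximization for theta at fixed mean, until the
    joint log-likelihood stabilizes.  theta is constrained to
    ``THETA_BOUNDS``; a fit ending on the upper bound (equidispersed,
    Poisson-limit data) is flagged via ``theta_boundary`` rather than
    silently accepted.
    """

    def __init__(self, spec: ModelSpec, tol: float = 1e-8, max_iter: int = 100):
        super().__init__(spec)
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _profile_theta(y, mu):
        lo, hi = np.log(THETA_BOUNDS)

        def nll(log_theta):
            return -nb_loglik(y, mu, np.exp(log_theta))

        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        return float(np.exp(res.x))

    def fit(self, X: pd.DataFrame, y=None):
        if y is None:
            y = X[self.spec.response]
        y = np.asarray(y)
        if not np.issubdtype(y.dtype, np.integer):
            if not np.allclose(y, np.round(y)):
                raise ValueError("negative-binomial response must be integer counts")
            y = np.round(y).astype(int)
        if (y < 0).any():
            raise ValueError("negative-binomial response must be non-negative")
        D = self._design(X, refit=True)
        if len(y) <= D.shape[1] + 1:
            raise ValueError(f"n={len(y)} too small for {D.shape[1]} columns + theta")
        _check_rank(D)

        m, v = y.mean(), y.var(ddof=1)
        theta = float(np.clip(m * m / max(v - m, 1e-6), *THETA_BOUNDS))
        ll_old = -np.inf
        start = None
        converged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(self.max_iter):
                fam = sm.families.NegativeBinomial(alpha=1.0 / theta)
                res = sm.GLM(y, D, family=fam).fit(start_params=start, maxiter=200)
                start = res.params.to_numpy()
                mu = np.asarray(res.mu)
                theta = self._profile_theta(y, mu)
                ll = nb_loglik(y, mu, theta)
                if abs(ll - ll_old) < self.tol * (abs(ll_old) + 1.0):
                    converged = True
                    break
                ll_old = ll
        # near the Poisson limit the theta profile flattens; flag a boundary
        # fit whenever the 95% profile interval for theta reaches the upper
        # bound (2 * log-likelihood drop < 1.92), i.e. the data cannot
        # distinguish the fit from equidispersion
        boundary = bool(
            theta <= THETA_BOUNDS[0] * 1.01
            or 2.0 * (ll - nb_loglik(y, mu, THETA_BOUNDS[1])) < 1.92
        )
        n = len(y)
        k = D.shape[1] + 1
        self._result = FitResult(
            label=self.spec.label,
            family="negbin",
            params=res.params,
            bse=res.bse,
            llf=ll,
            k=k,
            nobs=n,
            deviance=nb_deviance(y, mu, theta),
            df_resid=n - D.shape[1],
            dispersion=theta,
            converged=converged,
            theta_boundary=boundary,
            spec=self.spec,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        D = self._design(X, refit=False)
        return np.exp(D.to_numpy() @ self._result.params.to_numpy())


def fit_gaussian(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Fit a Gaussian model of ``spec`` on ``data`` (response taken from data)."""
    return GaussianGLM(spec).fit(data).result_


def fit_negbin(
    spec: ModelSpec, data: pd.DataFrame, tol: float = 1e-8, max_iter: int = 100
) -> FitResult:
    """Fit an NB2 log-link model of ``spec`` on ``data``."""
    return NegativeBinomialGLM(spec, tol=tol, max_iter=max_iter).fit(data).result_


def fit_model(spec: ModelSpec, data: pd.DataFrame, **kw) -> FitResult:
    if spec.family == "gaussian":
        return fit_gaussian(spec, data)
    return fit_negbin(spec, data, **kw)


def refit_negbin_fixed_theta(
    spec: ModelSpec, data: pd.DataFrame, theta: float
) -> FitResult:
    """Refit an NB model's coefficients with theta held fixed (deviance F-tests)."""
    y = np.asarray(data[spec.response])
    D = DesignEncoder(spec).fit(data).transform(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, D, family=sm.families.NegativeBinomial(alpha=1.0 / theta)).fit(
            maxiter=200
        )
    mu = np.asarray(res.mu)
    n = len(y)
    return FitResult(
        label=spec.label,
        family="negbin",
        params=res.params,
        bse=res.bse,
        llf=nb_loglik(y, mu, theta),
        k=D.shape[1] + 1,
        nobs=n,
        deviance=nb_deviance(y, mu, theta),
        df_resid=n - D.shape[1],
        dispersion=theta,
        converged=bool(res.converged),
        spec=spec,
    )
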
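"""Proper multiple imputation by normal linear regression and Rubin pooling.

The imputation step is the standard Bayesian normal-linear scheme under the
noninformative prior: for each imputation, the residual variance is drawn
from its scaled inverse-chi-square posterior, the coefficients from their
Gaussian posterior given that variance, and the missing values as linear
predictor plus Gaussian noise.  Per-imputation analysis estimates are pooled
with Rubin's rules (mean estimate, within/between variance, total variance
T = W + (1 + 1/m) B, and the classical small-m degrees of freedom).

The complete-records comparator and plain OLS fits live here too.  OLS is
implemented directly via the normal equations: the Monte-Carlo harness calls
it hundreds of thousands of times, and the per-call cost has to stay in the
microsecond range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import StudyDataset

__all__ = [
    "OLSFit",
    "MIResult",
    "ols_fit",
    "cra_estimate",
    "impute_normal",
    "impute_binary",
    "pool_rubin",
    "mi_analyze",
]


@dataclass(frozen=True)
class OLSFit:
    """A least-squares fit with coefficient covariance."""

    response: str
    predictors: tuple[str, ...]
    params: Mapping[str, float]  # includes "const"
    cov: np.ndarray  # ordered const, then predictors
    residual_variance: float  # RSS / (n - p - 1)
    nobs: int

    def estimate(self, name: str) -> float:
        return float(self.params[name])

    def se(self, name: str) -> float:
        order = ("const",) + self.predictors
        i = order.index(name)
        return float(math.sqrt(self.cov[i, i]))

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        dof = self.nobs - len(self.predictors) - 1
        t = sps.t.ppf(1 - alpha / 2, dof)
        est, se = self.estimate(name), self.se(name)
        return est - t * se, est + t * se


def _design(columns: Mapping[str, np.ndarray], predictors: Sequence[str], rows: np.ndarray) -> np.ndarray:
    X = np.empty((int(rows.sum()), len(predictors) + 1))
    X[:, 0] = 1.0
    for j, p in enumerate(predictors):
        X[:, j + 1] = columns[p][rows]
    return X


def _ols_core(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Coefficients, residual variance (n - p denominator incl. intercept), (X'X)^-1."""
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows to fit {p} parameters, got {n}")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular design matrix") from exc
    if np.linalg.cond(xtx) > 1e12:
        raise np.linalg.LinAlgError("singular design matrix")
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    return beta, sigma2, xtx_inv


def ols_fit(data: StudyDataset | pd.DataFrame, response: str, predictors: Sequence[str]) -> OLSFit:
    """OLS of ``response`` on ``predictors`` over rows complete for the fitted variables.

    Residual variance uses the unbiased ``n - p - 1`` denominator; the
    coefficient covariance is ``sigma^2 (X'X)^-1``.
    """
    df = data.df if isinstance(data, StudyDataset) else data
    predictors = tuple(predictors)
    cols = {c: df[c].to_numpy(dtype=float) for c in (response, *predictors)}
    rows = np.ones(len(df), dtype=bool)
    for v in cols.values():
        rows &= ~np.isnan(v)
    X = _design(cols, predictors, rows)
    y = cols[response][rows]
    beta, sigma2, xtx_inv = _ols_core(y, X)
    params = {"const": float(beta[0])}
    params.update({p: float(b) for p, b in zip(predictors, beta[1:])})
    return OLSFit(
        response=response,
        predictors=predictors,
        params=params,
        cov=sigma2 * xtx_inv,
        residual_variance=sigma2,
        nobs=int(rows.sum()),
    )


def cra_estimate(data: StudyDataset, response: str, predictors: Sequence[str]) -> OLSFit:
    """Complete-records analysis: OLS restricted to rows complete for the analysis model."""
    return ols_fit(data, response, predictors)


# ---------------------------------------------------------------------------
# Proper normal-linear imputation
# ---------------------------------------------------------------------------


def _posterior_imputations(
    y_obs: np.ndarray, X_obs: np.ndarray, X_mis: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """(m, n_mis) array of proper posterior-predictive draws for the missing entries."""
    beta_hat, _, xtx_inv = _ols_core(y_obs, X_obs)
    n, p = X_obs.shape
    rss = float(np.sum((y_obs - X_obs @ beta_hat) ** 2))
    dof = n - p
    chol = np.linalg.cholesky(xtx_inv)
    sigma2_draws = rss / rng.chisquare(dof, size=m)  # scaled inverse-chi-square
    z = rng.standard_normal((m, p))
    betas = beta_hat[None, :] + np.sqrt(sigma2_draws)[:, None] * (z @ chol.T)
    noise = rng.standard_normal((m, X_mis.shape[0])) * np.sqrt(sigma2_draws)[:, None]
    return betas @ X_mis.T + noise


def impute_normal(
    data: StudyDataset,
    target: str,
    predictors: Sequence[str],
    m: int,
    seed: int | np.random.Generator,
) -> list[pd.DataFrame]:
    """m completed copies of the dataset with ``target`` imputed from ``predictors``.

    Proper Bayesian draws under the noninformative prior.  A dataset with no
    missing entries in ``target`` is an error (not a no-op): silently copying
    would mask pipeline bugs upstream.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    df = data.df
    predictors = tuple(predictors)
    mis = df[target].isna().to_numpy()
    if not mis.any():
        raise ValueError(f"{target!r} has no missing entries to impute")
    for p in predictors:
        if df[p].isna().any():
            raise ValueError(f"imputation predictor {p!r} has missing entries")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {c: df[c].to_numpy(dtype=float) for c in (target, *predictors)}
    X_obs = _design(cols, predictors, ~mis)
    X_mis = _design(cols, predictors, mis)
    draws = _posterior_imputations(cols[target][~mis], X_obs, X_mis, m, rng)
    completed = []
    for j in range(m):
        dfj = df.copy()
        col = cols[target].copy()
        col[mis] = draws[j]
        dfj[target] = col
        completed.append(dfj)
    return completed


def impute_binary(
    data: StudyDataset,
    target: str,
    predictors: Sequence[str],
    m: int,
    seed: int | np.random.Generator,
) -> list[pd.DataFrame]:
    """Bayesian logistic imputation for a binary target (experimental).

    Coefficients are drawn from the asymptotic Gaussian posterior around the
    logistic MLE and missing values sampled as Bernoulli.  The continuous-case
    bias results transfer only approximately to binary variables; this method
    is provided for the binary-extension checks.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    import statsmodels.api as sm

    df = data.df
    predictors = tuple(predictors)
    mis = df[target].isna().to_numpy()
    if not mis.any():
        raise ValueError(f"{target!r} has no missing entries to impute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {c: df[c].to_numpy(dtype=float) for c in (target, *predictors)}
    X_obs = _design(cols, predictors, ~mis)
    X_mis = _design(cols, predictors, mis)
    fit = sm.Logit(cols[target][~mis], X_obs).fit(disp=0)
    chol = np.linalg.cholesky(np.asarray(fit.cov_params()))
    completed = []
    for _ in range(m):
        beta = np.asarray(fit.params) + chol @ rng.standard_normal(len(fit.params))
        prob = 1.0 / (1.0 + np.exp(-(X_mis @ beta)))
        dfj = df.copy()
        col = cols[target].copy()
        col[mis] = (rng.random(mis.sum()) < prob).astype(float)
        dfj[target] = col
        completed.append(dfj)
    return completed


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MIResult:
    """Pooled MI estimate with within/between/total variance.

    ``total_var = within_var + (1 + 1/m) * between_var`` holds exactly and
    ``se = sqrt(total_var)``; ``dof`` is the classical small-m value
    ``(m - 1)(1 + W / ((1 + 1/m) B))^2``.
    """

    pooled_estimate: float
    within_var: float
    between_var: float
    total_var: float
    se: float
    dof: float
    m: int
    per_imputation_estimates: tuple[float, ...]
    parameter: str = ""
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be at least 2")
        if self.between_var < 0:
            raise ValueError("between-imputation variance cannot be negative")
        expect = self.within_var + (1.0 + 1.0 / self.m) * self.between_var
        if not math.isclose(self.total_var, expect, rel_tol=1e-12, abs_tol=1e-300):
            raise ValueError("total variance must equal W + (1 + 1/m) B")

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        t = sps.t.ppf(1 - alpha / 2, self.dof) if math.isfinite(self.dof) else sps.norm.ppf(1 - alpha / 2)
        return self.pooled_estimate - t * self.se, self.pooled_estimate + t * self.se

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return "\n".join(
            [
                f"MI estimate of {self.parameter or 'parameter'} (m = {self.m})",
                f"  pooled estimate: {self.pooled_estimate:+.4f}  (SE {self.se:.4f})",
                f"  95% CI: ({lo:+.4f}, {hi:+.4f})  [dof {self.dof:.1f}]",
                f"  within-imputation variance:  {self.within_var:.6g}",
                f"  between-imputation variance: {self.between_var:.6g}",
                f"  total variance:              {self.total_var:.6g}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "pooled_estimate": self.pooled_estimate,
            "within_var": self.within_var,
            "between_var": self.between_var,
            "total_var": self.total_var,
            "se": self.se,
            "dof": self.dof,
            "m": self.m,
            "per_imputation_estimates": list(self.per_imputation_estimates),
            "parameter": self.parameter,
            "diagnostics": dict(self.diagnostics),
        }


def pool_rubin(
    estimates: Sequence[float], variances: Sequence[float], parameter: str = ""
) -> MIResult:
    """Rubin's rules pooling of per-imputation estimates and variances."""
    q = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if q.shape != v.shape:
        raise ValueError("estimates and variances must have equal length")
    m = q.size
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    qbar = float(q.mean())
    w = float(v.mean())
    b = float(q.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b > 0:
        dof = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        dof = math.inf
    return MIResult(
        pooled_estimate=qbar,
        within_var=w,
        between_var=b,
        total_var=t,
        se=math.sqrt(t),
        dof=dof,
        m=m,
        per_imputation_estimates=tuple(float(x) for x in q),
        parameter=parameter,
    )


# ---------------------------------------------------------------------------
# End-to-end MI analysis
# ---------------------------------------------------------------------------


def mi_analyze(
    data: StudyDataset,
    response: str,
    analysis_predictors: Sequence[str],
    imputation_target: str,
    imputation_predictors: Sequence[str],
    m: int = 100,
    seed: int | np.random.Generator = 0,
    parameter: str | None = None,
    binary_target: bool = False,
) -> MIResult:
    """Impute, fit the analysis model per completed dataset, and pool.

    ``parameter`` names the analysis-model coefficient to pool (default: the
    first analysis predictor, i.e. the exposure).  The diagnostics record the
    complete-records imputation-model fit, whose coefficient on the exposure
    is the value the MI estimator converges to as m grows.
    """
    analysis_predictors = tuple(analysis_predictors)
    imputation_predictors = tuple(imputation_predictors)
    parameter = parameter or analysis_predictors[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    df = data.df
    mis = df[imputation_target].isna().to_numpy()
    if not mis.any():
        raise ValueError(f"{imputation_target!r} has no missing entries to impute")
    names = {response, imputation_target, *analysis_predictors, *imputation_predictors}
    cols = {c: df[c].to_numpy(dtype=float) for c in names}
    for p in imputation_predictors:
        if np.isnan(cols[p]).any():
            raise ValueError(f"imputation predictor {p!r} has missing entries")

    # complete-records imputation-model fit (diagnostic alpha^OBS)
    X_obs = _design(cols, imputation_predictors, ~mis)
    X_mis = _design(cols, imputation_predictors, mis)
    y_imp = cols[imputation_target]
    if binary_target:
        import statsmodels.api as sm

        fit = sm.Logit(y_imp[~mis], X_obs).fit(disp=0)
        alpha_obs = {"const": float(fit.params[0])}
        alpha_obs.update({p: float(b) for p, b in zip(imputation_predictors, fit.params[1:])})
        chol = np.linalg.cholesky(np.asarray(fit.cov_params()))
        draws = np.empty((m, int(mis.sum())))
        for j in range(m):
            beta = np.asarray(fit.params) + chol @ rng.standard_normal(len(fit.params))
            prob = 1.0 / (1.0 + np.exp(-(X_mis @ beta)))
            draws[j] = (rng.random(mis.sum()) < prob).astype(float)
    else:
        beta_obs, _, _ = _ols_core(y_imp[~mis], X_obs)
        alpha_obs = {"const": float(beta_obs[0])}
        alpha_obs.update({p: float(b) for p, b in zip(imputation_predictors, beta_obs[1:])})
        draws = _posterior_imputations(y_imp[~mis], X_obs, X_mis, m, rng)

    # analysis model per completed dataset
    k = analysis_predictors.index(parameter) + 1 if parameter in analysis_predictors else 0
    estimates = np.empty(m)
    variances = np.empty(m)
    rows = np.ones(len(df), dtype=bool)
    X_ana_template = _design(cols, analysis_predictors, rows)
    y_ana = cols[response]
    target_in_analysis = imputation_target in analysis_predictors
    target_is_response = imputation_target == response
    for j in range(m):
        completed = y_imp.copy()
        completed[mis] = draws[j]
        if target_is_response:
            yj = completed
            Xj = X_ana_template
        else:
            yj = y_ana
            if target_in_analysis:
                Xj = X_ana_template.copy()
                Xj[:, analysis_predictors.index(imputation_target) + 1] = completed
            else:
                Xj = X_ana_template
        beta, sigma2, xtx_inv = _ols_core(yj, Xj)
        estimates[j] = beta[k]
        variances[j] = sigma2 * xtx_inv[k, k]

    result = pool_rubin(estimates, variances, parameter=parameter)
    return MIResult(
        **{
            **result.to_dict(),
            "per_imputation_estimates": tuple(estimates),
            "diagnostics": {
                "imputation_coefficients_obs": alpha_obs,
                "alpha_obs": alpha_obs.get(parameter),
                "n_observed": int((~mis).sum()),
                "n_missing": int(mis.sum()),
                "imputation_predictors": list(imputation_predictors),
            },
        }
    )
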
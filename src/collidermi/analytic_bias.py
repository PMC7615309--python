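"""Closed-form bias and standard-error results for MI with a collider auxiliary.

The setting: a substantive regression of outcome Y on exposure X, with Y (or
X) partially observed, and a candidate auxiliary variable W that shares a
common cause with both the partially observed variable (via Z) and its latent
missingness variable R (via unmeasured U).  Including W in the imputation
model opens the collider path and makes the missingness mechanism effectively
MNAR, biasing the MI estimator of the exposure coefficient.

This module implements, from exact population moments:

* the bias bound ``0 <= bias <= |beta_YX|W,R - beta_YX|``;
* the maximum-bias product formula in terms of direct effect sizes and error
  variances (outcome partially observed);
* the covariance-form version of that formula used for plug-in estimation on
  real data (with the 0.6 logit->probit conversion for terms involving the
  latent R);
* the analogous maximum-bias expression for the imputation-model coefficient
  alpha_1 when the exposure is partially observed;
* the four standard-error expressions for the MI-with-collider and
  complete-records estimators at the no-missingness and all-missing limits;
* the relative-precision measure ``100 (1 - SE_MI^2 / SE_CRA^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sem_core import (
    ConditionalModel,
    JointGaussian,
    PathModel,
    conditional_regression,
    implied_moments,
)

__all__ = [
    "LOGIT_TO_PROBIT",
    "BiasReport",
    "SummaryStats",
    "max_bias_outcome",
    "bias_bound",
    "max_bias_covform",
    "max_bias_exposure_alpha1",
    "se_profile",
    "relative_precision",
    "probit_from_logor",
    "logor_from_probit",
    "odds_ratio_from_probit",
    "selected_moments",
    "alpha_obs_limit",
]

#: Conversion factor between logistic and probit regression coefficients for a
#: binary indicator with a latent-normal representation.  Valid unless the
#: proportion of complete records is very close to 0 or 1.
LOGIT_TO_PROBIT = 0.6


class FormulaDomainError(ValueError):
    """Raised when a closed-form expression is evaluated outside its valid regime."""


# ---------------------------------------------------------------------------
# Logit <-> probit conversion
# ---------------------------------------------------------------------------


def probit_from_logor(log_odds_ratio: float, factor: float = LOGIT_TO_PROBIT) -> float:
    """Probit-scale coefficient corresponding to a log odds ratio."""
    return factor * log_odds_ratio


def logor_from_probit(probit_coef: float, factor: float = LOGIT_TO_PROBIT) -> float:
    """Log odds ratio corresponding to a probit-scale coefficient (inverse map)."""
    return probit_coef / factor


def odds_ratio_from_probit(probit_coef: float, factor: float = LOGIT_TO_PROBIT) -> float:
    """Odds ratio corresponding to a probit-scale coefficient."""
    return math.exp(logor_from_probit(probit_coef, factor))


# ---------------------------------------------------------------------------
# Summary statistics for the plug-in (covariance-form) formula
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStats:
    """Observable inputs to the covariance-form maximum-bias formula.

    The latent missingness variable R is standardized to mean 0 and variance 1
    (without loss of generality).  Covariances with R are not directly
    observable; they are recovered from the log odds ratios of logistic
    regressions of the observed-data indicator via
    ``Cov(., R) = factor * logOR * Var(.)``.

    Attributes
    ----------
    var_x, var_w : float
        Marginal variances of the exposure and the candidate collider.
    cov_yw : float
        Covariance of outcome and collider (estimated on complete records
        when the outcome is partially observed).
    logor_x_r, logor_w_r : float
        Log odds ratios from logistic regressions of the observed-data
        indicator on X, and on W (adjusted for X).
    factor : float
        Logit->probit conversion constant, default 0.6.
    notes : tuple of str
        Free-text caveats carried into downstream reports (e.g. whether the
        collider log odds ratio is conditional rather than marginal).
    """

    var_x: float
    var_w: float
    cov_yw: float
    logor_x_r: float
    logor_w_r: float
    factor: float = LOGIT_TO_PROBIT
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.var_x > 0 and self.var_w > 0):
            raise ValueError("variances must be positive")

    @property
    def cov_xr(self) -> float:
        return self.factor * self.logor_x_r * self.var_x

    @property
    def cov_wr(self) -> float:
        return self.factor * self.logor_w_r * self.var_w

    @classmethod
    def from_path_model(cls, model: PathModel, factor: float = LOGIT_TO_PROBIT) -> "SummaryStats":
        """Population summary statistics implied by a path model.

        Standardizes the latent R to unit variance and converts the implied
        Cov(., R) terms back to the log-odds-ratio inputs the formula expects,
        so the covariance-form route can be cross-checked against the direct
        effect-size route on the same model.
        """
        joint = implied_moments(model)
        x = model.role("exposure")
        w = model.role("collider")
        y = model.role("outcome")
        r = model.role("missingness")
        sd_r = math.sqrt(joint.var(r))
        cov_xr = joint.covariance(x, r) / sd_r
        cov_wr = joint.covariance(w, r) / sd_r
        return cls(
            var_x=joint.var(x),
            var_w=joint.var(w),
            cov_yw=joint.covariance(y, w),
            logor_x_r=cov_xr / (factor * joint.var(x)),
            logor_w_r=cov_wr / (factor * joint.var(w)),
            factor=factor,
        )

    @classmethod
    def from_mapping(cls, data: Mapping) -> "SummaryStats":
        """Build from a plain mapping (e.g. parsed JSON/YAML).

        Odds ratios may be given as ``or_x_r`` / ``or_w_r`` instead of log
        odds ratios.
        """
        d = dict(data)
        if "logor_x_r" not in d and "or_x_r" in d:
            d["logor_x_r"] = math.log(float(d.pop("or_x_r")))
        if "logor_w_r" not in d and "or_w_r" in d:
            d["logor_w_r"] = math.log(float(d.pop("or_w_r")))
        allowed = {"var_x", "var_w", "cov_yw", "logor_x_r", "logor_w_r", "factor"}
        kwargs = {k: float(v) for k, v in d.items() if k in allowed}
        notes = tuple(d.get("notes", ()))
        return cls(notes=notes, **kwargs)


# ---------------------------------------------------------------------------
# Maximum bias, outcome partially observed
# ---------------------------------------------------------------------------


def _outcome_roles(model: PathModel) -> tuple[str, str, str, str, str, str]:
    try:
        return (
            model.role("outcome"),
            model.role("exposure"),
            model.role("predictor"),
            model.role("collider"),
            model.role("unmeasured"),
            model.role("missingness"),
        )
    except KeyError as exc:
        raise FormulaDomainError(f"model is missing role {exc}") from exc


def max_bias_outcome(model: PathModel) -> float:
    """Maximum bias of the MI estimator of the exposure coefficient.

    Applies to the outcome-partially-observed M-structure (``fig1``-shaped
    models): W (collider) and X are imputation-model predictors for Y, and the
    bias attains its maximum as the missing proportion tends to 1.  In terms
    of direct effect sizes and error variances:

    ``b_RX b_RU b_WU b_YZ b_WZ s2_Z s2_U /
    [(b_RU^2 s2_U + s2_R)(b_WZ^2 s2_Z + s2_W) + b_WU^2 s2_U s2_R]``

    The sign of the product is preserved; the value does not depend on the
    exposure coefficient itself.
    """
    y, x, z, w, u, r = _outcome_roles(model)
    # sanity check on the scenario shape: Y must not cause its own missingness
    if y in model.parents.get(r, ()):
        raise FormulaDomainError("outcome formula requires missingness unrelated to Y given its parents")
    if x not in model.parents.get(r, ()):
        raise FormulaDomainError("outcome formula requires an X -> R edge (exposure drives missingness)")
    b_rx = model.coefficient(r, x)
    b_ru = model.coefficient(r, u)
    b_wu = model.coefficient(w, u)
    b_yz = model.coefficient(y, z)
    b_wz = model.coefficient(w, z)
    s2 = {v: float(model.error_variances[v]) for v in (z, u, w, r)}
    num = b_rx * b_ru * b_wu * b_yz * b_wz * s2[z] * s2[u]
    den = (b_ru**2 * s2[u] + s2[r]) * (b_wz**2 * s2[z] + s2[w]) + b_wu**2 * s2[u] * s2[r]
    return num / den


def bias_bound(
    model: PathModel, imputation_predictors: Sequence[str] | None = None
) -> tuple[float, float]:
    """Bias bound ``(0, |beta_YX|preds,R - beta_YX|preds|)`` for the MI estimator.

    Both conditional coefficients are computed by Gaussian conditioning on the
    implied joint distribution including the latent R.  With the default
    predictors {X, W} in a ``fig1``-shaped model this equals
    ``|beta_YX|W,R - beta_YX|`` (Cov(X, W) = 0 there, so conditioning on W
    leaves the exposure coefficient unchanged), and its magnitude coincides
    with :func:`max_bias_outcome`.
    """
    y, x, z, w, u, r = _outcome_roles(model)
    if imputation_predictors is None:
        imputation_predictors = (x, w)
    preds = list(imputation_predictors)
    if x not in preds:
        raise ValueError("imputation predictors must include the exposure")
    joint = implied_moments(model)
    full = conditional_regression(joint, y, preds + [r])
    base = conditional_regression(joint, y, preds)
    return 0.0, abs(full.coefficient(x) - base.coefficient(x))


def max_bias_covform(stats: SummaryStats) -> float:
    """Maximum bias from the covariance-form (plug-in) formula.

    ``Cov(X,R) Cov(W,R) Cov(Y,W) /
    [{Var(X) - Cov^2(X,R)} Var(W) - Var(X) Cov^2(W,R)]``

    with R standardized to unit variance and the Cov(., R) terms recovered
    from log odds ratios via the 0.6 rule.  Raises
    :class:`FormulaDomainError` when the denominator is not positive (the
    plug-in inputs are then outside the formula's valid regime).
    """
    cov_xr = stats.cov_xr
    cov_wr = stats.cov_wr
    num = cov_xr * cov_wr * stats.cov_yw
    den = (stats.var_x - cov_xr**2) * stats.var_w - stats.var_x * cov_wr**2
    if den <= 0:
        raise FormulaDomainError(
            "covariance-form denominator is non-positive; the implied Cov(., R) terms "
            "are too large relative to Var(X) and Var(W) for the formula to apply"
        )
    return num / den


# ---------------------------------------------------------------------------
# Maximum bias, exposure partially observed
# ---------------------------------------------------------------------------


def max_bias_exposure_alpha1(model: PathModel) -> float:
    """Maximum bias of the imputation-model coefficient on Y when X is imputed.

    Applies to the exposure-partially-observed scenario (``fig4``-shaped
    models), where the imputation model is ``E(X) = a0 + a1 Y + a2 W``.  With
    ``A = Cov^2(R, W) / (Var(R) Var(W))``, the maximum bias of the estimate of
    ``a1`` from complete records is

    ``A {Var(Y) Cov(Y,X|W) - Cov(Y,X) Var(Y|W)} /
    [Var(Y|W) {Var(Y|W) - A Var(Y)}]``

    with every moment taken from the implied joint distribution.
    """
    y = model.role("outcome")
    x = model.role("exposure")
    w = model.role("collider")
    r = model.role("missingness")
    if x in model.parents.get(r, ()):
        raise FormulaDomainError("exposure-case formula requires missingness not directly caused by X")
    joint = implied_moments(model)
    var_r = joint.var(r)
    var_w = joint.var(w)
    var_y = joint.var(y)
    cov_rw = joint.covariance(r, w)
    A = cov_rw**2 / (var_r * var_w)
    var_y_w = joint.conditional_variance(y, [w])
    cov_yx_w = joint.conditional_covariance(y, x, [w])
    cov_yx = joint.covariance(y, x)
    den = var_y_w * (var_y_w - A * var_y)
    if abs(den) < 1e-300:
        raise FormulaDomainError("degenerate denominator in exposure-case maximum bias")
    return A * (var_y * cov_yx_w - cov_yx * var_y_w) / den


# ---------------------------------------------------------------------------
# Standard-error profile and relative precision
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasReport:
    """Analytic bias/SE profile of MI-with-collider versus complete records.

    All standard errors refer to the estimator of the exposure coefficient
    with ``n_observed`` records carrying an observed outcome; ``se_*_at_0``
    are the values when no data are missing and ``se_*_limit`` the limits as
    the missing proportion tends to 1.
    """

    max_bias: float
    bias_lower: float
    direction: int
    se_mi_at_0: float
    se_mi_limit: float
    se_cra_at_0: float
    se_cra_limit: float
    relative_precision_pct: float
    n_observed: int
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bias_lower != 0.0:
            raise ValueError("lower bias bound is identically 0")
        for se in (self.se_mi_at_0, self.se_mi_limit, self.se_cra_at_0, self.se_cra_limit):
            if not se > 0:
                raise ValueError("standard errors must be positive")
        if self.se_cra_limit < self.se_cra_at_0 - 1e-12:
            raise ValueError("complete-records SE cannot shrink as missingness grows")

    def summary(self) -> str:
        lines = [
            "Collider-auxiliary bias/SE profile",
            "----------------------------------",
            f"observed records (n):            {self.n_observed}",
            f"maximum bias (as pi0 -> 1):      {self.max_bias:+.4f}",
            f"bias bound:                      [0, {abs(self.max_bias):.4f}]",
            f"SE of MI estimator at pi0 = 0:   {self.se_mi_at_0:.4f}",
            f"SE of MI estimator as pi0 -> 1:  {self.se_mi_limit:.4f}",
            f"SE of CRA estimator at pi0 = 0:  {self.se_cra_at_0:.4f}",
            f"SE of CRA estimator as pi0 -> 1: {self.se_cra_limit:.4f}",
            f"relative precision gain of MI over CRA as pi0 -> 1: {self.relative_precision_pct:.1f}%",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "max_bias": self.max_bias,
            "bias_lower": self.bias_lower,
            "direction": self.direction,
            "se_mi_at_0": self.se_mi_at_0,
            "se_mi_limit": self.se_mi_limit,
            "se_cra_at_0": self.se_cra_at_0,
            "se_cra_limit": self.se_cra_limit,
            "relative_precision_pct": self.relative_precision_pct,
            "n_observed": self.n_observed,
            "metadata": dict(self.metadata),
        }


def se_profile(model: PathModel, n_observed: int) -> BiasReport:
    """Analytic SE endpoints and maximum bias for an outcome-missing scenario.

    The MI estimator uses imputation predictors {X, W}; the comparator is the
    complete-records (equivalently MI-with-X-only) estimator.  At no
    missingness the MI SE is ``sqrt([Var(Y) - b^2 Var(X) - Cov^2(Y,W)/Var(W)]
    / (n Var(X)))`` and the CRA SE is ``sqrt([Var(Y) - b^2 Var(X)] /
    (n Var(X)))``; in the all-missing limit they tend to
    ``sqrt(Var(Y|X,W,R) / (n Var(X|W,R)))`` and
    ``sqrt([Var(Y) - b^2 Var(X)] / (n [Var(X) - Cov^2(X,R)/Var(R)]))``
    respectively, where b is the substantive exposure coefficient.
    """
    if n_observed < 2:
        raise ValueError("n_observed must be at least 2")
    y, x, z, w, u, r = _outcome_roles(model)
    joint = implied_moments(model)
    beta_yx = conditional_regression(joint, y, [x]).coefficient(x)
    var_y = joint.var(y)
    var_x = joint.var(x)
    var_w = joint.var(w)
    cov_yw = joint.covariance(y, w)
    cov_xr = joint.covariance(x, r)
    var_r = joint.var(r)
    n = float(n_observed)

    se_mi_0 = math.sqrt((var_y - beta_yx**2 * var_x - cov_yw**2 / var_w) / (n * var_x))
    resid_full = joint.conditional_variance(y, [x, w, r])
    var_x_wr = joint.conditional_variance(x, [w, r])
    se_mi_1 = math.sqrt(resid_full / (n * var_x_wr))
    cra_num = var_y - beta_yx**2 * var_x
    se_cra_0 = math.sqrt(cra_num / (n * var_x))
    var_x_r = var_x - cov_xr**2 / var_r
    se_cra_1 = math.sqrt(cra_num / (n * var_x_r))

    mb = max_bias_outcome(model)
    return BiasReport(
        max_bias=mb,
        bias_lower=0.0,
        direction=int(math.copysign(1, mb)) if mb != 0 else 0,
        se_mi_at_0=se_mi_0,
        se_mi_limit=se_mi_1,
        se_cra_at_0=se_cra_0,
        se_cra_limit=se_cra_1,
        relative_precision_pct=relative_precision(se_mi_1, se_cra_1),
        n_observed=int(n_observed),
        metadata={"beta_yx": beta_yx, "imputation_predictors": [x, w]},
    )


# ---------------------------------------------------------------------------
# Exact selected-population (complete-records) moments
# ---------------------------------------------------------------------------


def selected_moments(model: PathModel, pi0: float) -> JointGaussian:
    """First two moments of all variables among complete records at a given pi0.

    Records are complete when the latent R falls at or below the threshold
    with exceedance probability ``pi0``.  Because every variable has a linear
    Gaussian regression on R with residuals independent of R, selection on R
    shifts means along ``Cov(V, R)/Var(R)`` and shrinks the covariance by a
    rank-one term proportional to the variance lost by truncating R:

    ``Cov_sel(Vi, Vj) = Cov(Vi, Vj) - g_i g_j (V_R - Var(R | R <= r))``

    with ``g_i = Cov(Vi, R) / V_R`` and the truncated-normal variance in
    closed form.  The selected joint distribution is not normal, but these
    moments are exact, and population least squares on them (via
    :func:`collidermi.sem_core.conditional_regression`) gives the exact
    probability limits of complete-records OLS coefficients — in particular
    the imputation-model coefficient the MI estimator converges to at any
    intermediate missing proportion, not just the pi0 -> 1 bound.
    """
    if not 0.0 <= pi0 < 1.0:
        raise ValueError("pi0 must lie in [0, 1)")
    joint = implied_moments(model)
    if pi0 == 0.0:
        return joint
    from scipy import stats as sps

    r = model.role("missingness")
    v_r = joint.var(r)
    a = sps.norm.ppf(1.0 - pi0)  # standardized threshold
    trunc = sps.truncnorm(-math.inf, a)
    mean_shift = math.sqrt(v_r) * float(trunc.mean())
    var_sel_r = v_r * float(trunc.var())
    g = np.array([joint.covariance(n, r) for n in joint.names]) / v_r
    mean = joint.mean + g * mean_shift
    cov = joint.cov - np.outer(g, g) * (v_r - var_sel_r)
    return JointGaussian(names=joint.names, mean=mean, cov=cov)


def alpha_obs_limit(
    model: PathModel, pi0: float, imputation_predictors: Sequence[str] | None = None
) -> ConditionalModel:
    """Probability limit of the complete-records imputation-model fit at ``pi0``.

    For outcome-missing scenarios with predictors {X, W} this is the value the
    MI estimator of the exposure coefficient converges to (in m and n); its
    coefficient on X minus the substantive coefficient is the exact bias curve
    traced against the missing proportion, with the product-formula maximum
    recovered as pi0 -> 1.
    """
    y = model.role("outcome")
    x = model.role("exposure")
    if imputation_predictors is None:
        imputation_predictors = (x, model.role("collider"))
    sel = selected_moments(model, pi0)
    return conditional_regression(sel, y, list(imputation_predictors))


def relative_precision(se_mi: float, se_cra: float) -> float:
    """Relative increase in precision of MI over CRA: ``100 (1 - SE_MI^2/SE_CRA^2)``."""
    if not (se_mi > 0 and se_cra > 0):
        raise ValueError("standard errors must be positive")
    return 100.0 * (1.0 - se_mi**2 / se_cra**2)
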
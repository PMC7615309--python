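"""Two-step applied procedure for assessing collider auxiliaries on real data.

Step 1 (:func:`screen_auxiliaries`) explores pairwise relationships between
the candidate auxiliaries, the exposure and the observed-data indicator,
fitting linear or logistic regressions according to a user-declared causal
ordering (causal direction is a judgment call the tool does not automate).
The collider signature is an auxiliary whose association with the
missingness indicator *strengthens* when another candidate is conditioned
on: conditioning on a collider opens the path through the shared unmeasured
cause.

Step 2 (:func:`plugin_max_bias`) plugs observable summary statistics into the
covariance-form maximum-bias formula and attaches an approximate confidence
interval, ``max bias +/- 1.96 x SE`` of the MI estimate that includes the
collider.

:func:`compare_strategies` reproduces the strategy-comparison table: CRA and
MI with each admissible auxiliary set, one row per strategy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import analytic_bias as ab
from .mi_engine import cra_estimate, mi_analyze, ols_fit
from .simulate import StudyDataset

__all__ = [
    "ScreenTable",
    "PluginBiasResult",
    "screen_auxiliaries",
    "plugin_max_bias",
    "estimate_summary_stats",
    "compare_strategies",
]

#: The strengthening of an association upon conditioning must exceed this
#: many standard errors of the *change* before a candidate is flagged as a
#: collider.  For nested fits the sampling SD of the change in the estimate is
#: approximately sqrt(se_adj^2 - se_unadj^2) (floored at 0.2 se_adj), which
#: guards against noise-driven "strengthening" of two null associations.
COLLIDER_FLAG_SE_MARGIN = 2.0


@dataclass
class ScreenTable:
    """Step-1 pairwise screening results.

    ``table`` has one row per fitted (explanatory, dependent) pair: model
    family, estimate (slope or log odds ratio), 95% CI, adjustment set, and —
    for auxiliary -> missingness-indicator pairs — the same association
    conditioned on each other candidate collider.  ``collider_flags`` lists
    candidates whose conditioning strengthened another auxiliary's
    association with missingness.
    """

    table: pd.DataFrame
    collider_flags: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, lineterminator="\n")
        return path

    def summary(self) -> str:
        lines = ["Auxiliary-variable screen", "-------------------------"]
        for _, row in self.table.iterrows():
            if row.get("error"):
                lines.append(f"{row['explanatory']} -> {row['dependent']}: ERROR ({row['error']})")
                continue
            adj = f" | {row['adjusted_for']}" if row["adjusted_for"] else ""
            lines.append(
                f"{row['explanatory']} -> {row['dependent']}{adj} [{row['family']}]: "
                f"{row['estimate']:+.3f} (95% CI {row['ci_low']:+.3f}, {row['ci_high']:+.3f})"
            )
        if self.collider_flags:
            lines.append(f"collider signature flagged for: {', '.join(self.collider_flags)}")
        else:
            lines.append("no collider signature flagged")
        return "\n".join(lines)


def _fit_pair(
    df: pd.DataFrame, dependent: str, explanatory: str, adjust: Sequence[str]
) -> dict:
    """One screening regression; logistic when the dependent is binary."""
    cols = [dependent, explanatory, *adjust]
    sub = df[cols].dropna()
    row = {
        "explanatory": explanatory,
        "dependent": dependent,
        "adjusted_for": "+".join(adjust),
        "n": len(sub),
        "error": "",
    }
    try:
        yv = sub[dependent].to_numpy(dtype=float)
        if np.nanstd(yv) == 0:
            raise ValueError("dependent variable has zero variance")
        binary = set(np.unique(yv[~np.isnan(yv)])) <= {0.0, 1.0}
        X = sm.add_constant(sub[[explanatory, *adjust]].to_numpy(dtype=float))
        if binary:
            fit = sm.Logit(yv, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                raise ValueError("logistic fit did not converge (possible separation)")
            family = "logistic"
        else:
            fit = sm.OLS(yv, X).fit()
            family = "linear"
        est = float(fit.params[1])
        se = float(fit.bse[1])
        row.update(
            family=family,
            estimate=est,
            se=se,
            ci_low=est - 1.96 * se,
            ci_high=est + 1.96 * se,
        )
    except Exception as exc:  # per-cell errors are reported, not fatal
        row.update(family="", estimate=math.nan, se=math.nan, ci_low=math.nan, ci_high=math.nan, error=str(exc))
    return row


def screen_auxiliaries(
    data: StudyDataset | pd.DataFrame,
    ordering: Sequence[str] | Mapping,
    r_ind: str = "R_ind",
    flag_margin: float = COLLIDER_FLAG_SE_MARGIN,
) -> ScreenTable:
    """Step-1 screen of candidate auxiliaries against the causal ordering.

    ``ordering`` lists the screened variables from most upstream to most
    downstream (a mapping with key ``"order"`` is also accepted, as parsed
    from a YAML spec).  For each ordered pair, the later variable is regressed
    on the earlier one, adjusting for all variables that precede the
    explanatory variable; the missingness indicator is always the most
    downstream dependent.  For each auxiliary -> indicator association, the
    fit is repeated conditioning additionally on each other downstream
    candidate; a candidate is flagged as a potential collider when
    conditioning on it strengthens the association by more than
    ``flag_margin`` standard errors of the change in the estimate.
    """
    df = data.df if isinstance(data, StudyDataset) else data
    if isinstance(ordering, Mapping):
        ordering = list(ordering.get("order", ()))
    ordering = list(ordering)
    unknown = [v for v in ordering if v not in df.columns]
    if unknown:
        raise KeyError(f"ordering names unknown columns: {unknown}")
    if r_ind not in df.columns:
        raise KeyError(f"missingness indicator column {r_ind!r} not found")
    # deterministic under row permutations: fits depend only on the joint rows
    rows: list[dict] = []
    for i, explanatory in enumerate(ordering):
        adjust = ordering[:i]
        for dependent in ordering[i + 1 :] + [r_ind]:
            rows.append(_fit_pair(df, dependent, explanatory, adjust))
    # collider probes: aux -> R_ind additionally conditioned on a later candidate
    flags: list[str] = []
    for i, aux in enumerate(ordering):
        base = next(
            r for r in rows if r["explanatory"] == aux and r["dependent"] == r_ind
        )
        if base["error"]:
            continue
        for candidate in ordering[i + 1 :]:
            probe = _fit_pair(df, r_ind, aux, ordering[:i] + [candidate])
            probe["adjusted_for"] = "+".join(ordering[:i] + [candidate])
            probe["probe_for_collider"] = candidate
            rows.append(probe)
            if probe["error"]:
                continue
            se_change = max(
                math.sqrt(max(probe["se"] ** 2 - base["se"] ** 2, 0.0)), 0.2 * probe["se"]
            )
            strengthened = abs(probe["estimate"]) - abs(base["estimate"]) > flag_margin * se_change
            if strengthened and candidate not in flags:
                flags.append(candidate)
    table = pd.DataFrame(rows)
    if "probe_for_collider" not in table.columns:
        table["probe_for_collider"] = ""
    table["probe_for_collider"] = table["probe_for_collider"].fillna("")
    return ScreenTable(
        table=table,
        collider_flags=tuple(flags),
        meta={"ordering": ordering, "r_ind": r_ind, "flag_margin": flag_margin},
    )


# ---------------------------------------------------------------------------
# Step 2: plug-in maximum bias
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PluginBiasResult:
    """Plug-in maximum bias with approximate confidence interval."""

    max_bias: float
    se_reference: float
    ci_low: float
    ci_high: float
    inputs: ab.SummaryStats
    direction_note: str = ""
    z: float = 1.96

    def __post_init__(self) -> None:
        if not math.isclose(self.ci_low, self.max_bias - self.z * self.se_reference, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("ci_low must equal max_bias - z * se_reference")
        if not math.isclose(self.ci_high, self.max_bias + self.z * self.se_reference, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("ci_high must equal max_bias + z * se_reference")

    def summary(self) -> str:
        lines = [
            "Plug-in maximum bias from including the collider auxiliary",
            "----------------------------------------------------------",
            f"maximum bias:        {self.max_bias:+.3f}",
            f"approximate 95% CI:  ({self.ci_low:+.3f}, {self.ci_high:+.3f})"
            f"   [max bias +/- {self.z:.2f} x SE {self.se_reference:.3f}]",
        ]
        if self.direction_note:
            lines.append(f"direction:           {self.direction_note}")
        for note in self.inputs.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "max_bias": self.max_bias,
            "se_reference": self.se_reference,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "z": self.z,
            "direction_note": self.direction_note,
            "inputs": {
                "var_x": self.inputs.var_x,
                "var_w": self.inputs.var_w,
                "cov_yw": self.inputs.cov_yw,
                "logor_x_r": self.inputs.logor_x_r,
                "logor_w_r": self.inputs.logor_w_r,
                "factor": self.inputs.factor,
                "notes": list(self.inputs.notes),
            },
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def plugin_max_bias(
    stats: ab.SummaryStats,
    se_reference: float,
    analysis_estimate: float | None = None,
    z: float = 1.96,
) -> PluginBiasResult:
    """Covariance-form maximum bias with approximate CI.

    ``se_reference`` is the SE of the MI estimate that includes the collider,
    used as an approximate SE of the maximum bias.  When the sign of the
    substantive analysis estimate is supplied, the result is annotated with
    whether the bias points toward or away from the null.
    """
    if not se_reference > 0:
        raise ValueError("se_reference must be positive")
    mb = ab.max_bias_covform(stats)
    note = ""
    if analysis_estimate is not None and mb != 0:
        toward = (analysis_estimate < 0) == (mb > 0)
        note = "towards the null" if toward else "away from the null"
    return PluginBiasResult(
        max_bias=mb,
        se_reference=float(se_reference),
        ci_low=mb - z * se_reference,
        ci_high=mb + z * se_reference,
        inputs=stats,
        direction_note=note,
        z=z,
    )


def estimate_summary_stats(
    data: StudyDataset | pd.DataFrame,
    roles: Mapping[str, str],
    r_ind: str = "R_ind",
    factor: float = ab.LOGIT_TO_PROBIT,
) -> ab.SummaryStats:
    """Observable summary statistics for the plug-in formula.

    ``roles`` maps ``exposure``, ``collider`` and ``outcome`` to column names.
    Var(X) uses the binomial variance ``p (1 - p)`` when the exposure is
    binary; Var(W) uses all records; Cov(Y, W) uses complete records only
    (the outcome is partially observed); the log odds ratios come from
    logistic regressions of the observed-data indicator on X, and on W
    adjusted for X — the adjusted (conditional) form is what the screening
    step reports for the collider, and that substitution is carried into the
    formula with an explanatory note.
    """
    df = data.df if isinstance(data, StudyDataset) else data
    missing = [k for k in ("exposure", "collider", "outcome") if k not in roles]
    if missing:
        raise KeyError(f"roles must assign {missing}")
    x, w, y = roles["exposure"], roles["collider"], roles["outcome"]
    if r_ind not in df.columns:
        raise KeyError(f"missingness indicator column {r_ind!r} not found")
    ydata = df[y]
    if ydata.notna().sum() == 0:
        raise ValueError("outcome is entirely missing; covariance with the collider is undefined")
    if ydata.isna().sum() == 0:
        raise ValueError("outcome has no missing values; missingness log odds ratios are undefined")
    xv = df[x].to_numpy(dtype=float)
    wv = df[w].to_numpy(dtype=float)
    rv = df[r_ind].to_numpy(dtype=float)
    if set(np.unique(xv[~np.isnan(xv)])) <= {0.0, 1.0}:
        p = float(np.nanmean(xv))
        var_x = p * (1.0 - p)
    else:
        var_x = float(np.nanvar(xv, ddof=1))
    var_w = float(np.nanvar(wv, ddof=1))
    complete = ydata.notna().to_numpy()
    cov_yw = float(np.cov(ydata.to_numpy(dtype=float)[complete], wv[complete], ddof=1)[0, 1])
    logor_x = float(sm.Logit(rv, sm.add_constant(xv)).fit(disp=0).params[1])
    X_wx = sm.add_constant(np.column_stack([wv, xv]))
    logor_w = float(sm.Logit(rv, X_wx).fit(disp=0).params[1])
    return ab.SummaryStats(
        var_x=var_x,
        var_w=var_w,
        cov_yw=cov_yw,
        logor_x_r=logor_x,
        logor_w_r=logor_w,
        factor=factor,
        notes=(
            "collider log odds ratio is conditional on the exposure, substituted "
            "into a formula written for the marginal Cov(W, R)",
        ),
    )


# ---------------------------------------------------------------------------
# Strategy comparison
# ---------------------------------------------------------------------------

_STRATEGIES = ("CRA", "MI", "MI+Z", "MI+W", "MI+Z+W")


def compare_strategies(
    data: StudyDataset,
    roles: Mapping[str, str],
    strategies: Sequence[str] = _STRATEGIES,
    m: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Exposure-coefficient estimates under CRA and MI with each auxiliary set.

    ``roles`` maps ``outcome``, ``exposure``, ``predictor`` (the direct
    predictor Z) and ``collider`` (W) to column names.  Every imputation model
    includes the exposure; auxiliary sets follow the strategy label.  Returns
    one row per strategy with estimate, SE and 95% CI.
    """
    y, x = roles["outcome"], roles["exposure"]
    z, w = roles.get("predictor"), roles.get("collider")
    aux_sets = {
        "CRA": None,
        "MI": (),
        "MI+Z": (z,),
        "MI+W": (w,),
        "MI+Z+W": (z, w),
    }
    rng = np.random.default_rng(seed)
    no_missing = not data.df[y].isna().any()
    rows = []
    for strategy in strategies:
        if strategy not in aux_sets:
            raise ValueError(f"unknown strategy {strategy!r}; choose from {sorted(aux_sets)}")
        aux = aux_sets[strategy]
        if aux is not None and any(a is None for a in aux):
            raise ValueError(f"strategy {strategy!r} needs roles for its auxiliaries")
        if strategy == "CRA" or no_missing:
            fit = cra_estimate(data, y, (x,)) if strategy == "CRA" else ols_fit(data, y, (x,))
            est, se = fit.estimate(x), fit.se(x)
            lo, hi = fit.conf_int(x)
            mm = None
        else:
            res = mi_analyze(
                data,
                response=y,
                analysis_predictors=(x,),
                imputation_target=y,
                imputation_predictors=(x, *aux),
                m=m,
                seed=rng,
                parameter=x,
            )
            est, se = res.pooled_estimate, res.se
            lo, hi = res.conf_int()
            mm = m
        rows.append(
            {"strategy": strategy, "estimate": est, "se": se, "ci_low": lo, "ci_high": hi, "m": mm}
        )
    return pd.DataFrame(rows)
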
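"""Monte-Carlo harness: missingness sweeps, effect-size grids, SE crossover.

Conventions
-----------
* The number of **observed** outcome records is held fixed along a missing-
  proportion sweep; total sample size is inflated to ``n / (1 - pi0)``.  This
  keeps the analytic SE endpoint formulas (which are stated per observed
  record) comparable across the sweep.  The alternative (fixed total n) gives
  different SE curves.
* Analytic columns (maximum-bias and SE endpoint overlays) are computed from
  exact implied moments and are independent of the replicate count and seed.
* Empirical SEs are standard deviations of point estimates across replicate
  datasets; each cell records its seed and replicate count.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import analytic_bias as ab
from .mi_engine import _design, _ols_core, mi_analyze, ols_fit
from .sem_core import PathModel, build_path_model, conditional_regression, implied_moments
from .simulate import (
    MissingnessSpec,
    _simulate_matrix,
    impose_missingness,
    missingness_threshold,
    simulate_complete,
)

__all__ = [
    "SweepResult",
    "sweep_pi0",
    "sweep_effects",
    "find_se_crossover",
    "replicate_estimates",
]


@dataclass
class SweepResult:
    """Tidy per-cell results of a sweep, plus run metadata."""

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False, lineterminator="\n")
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"meta": self.meta, "cells": self.table.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
        return path


# ---------------------------------------------------------------------------
# Replicate engine
# ---------------------------------------------------------------------------


def _scenario_setup(model: PathModel, masked_role: str) -> dict:
    """Analysis/imputation variable names for a scenario.

    Outcome-missing scenarios impute Y from {X, W}; exposure-missing
    scenarios impute X from {Y, W}.  The analysis model is always Y ~ X.
    """
    y = model.role("outcome")
    x = model.role("exposure")
    w = model.role("collider")
    masked = model.role(masked_role)
    imp_preds = (x, w) if masked == y else (y, w)
    return {"response": y, "exposure": x, "collider": w, "masked": masked, "imputation_predictors": imp_preds}


def replicate_estimates(
    model: PathModel,
    pi0: float,
    n_observed: int,
    reps: int,
    m: int,
    seed_sequences: Sequence[np.random.SeedSequence],
    masked_role: str = "outcome",
    imputation_predictors: Sequence[str] | None = None,
    calibration: str = "theoretical",
    run_mi: bool = True,
) -> pd.DataFrame:
    """MI and CRA point estimates of the exposure coefficient over replicates.

    One row per replicate with columns ``mi`` (pooled MI estimate), ``cra``,
    ``mi_se_rubin`` (Rubin total SE), ``mi_between_var`` (between-imputation
    variance B) and ``alpha_obs`` (complete-records imputation-model
    coefficient on the exposure, where defined).  At ``pi0 = 0`` the MI column
    holds the imputation-model coefficient fitted to the full data, which is
    what the MI estimator equals with no missingness.

    With ``run_mi=False`` the imputation step is skipped and the ``mi`` column
    holds the complete-records imputation-model coefficient itself — the
    large-imputation-number limit of the MI estimator — which is much cheaper
    and free of finite-m imputation noise.  Outcome-missing scenarios only.
    """
    setup = _scenario_setup(model, masked_role)
    if imputation_predictors is not None:
        setup["imputation_predictors"] = tuple(imputation_predictors)
    y, x = setup["response"], setup["exposure"]
    masked = setup["masked"]
    n_total = n_observed if pi0 <= 0 else int(round(n_observed / (1.0 - pi0)))
    if run_mi is False and pi0 > 0 and masked != y:
        raise ValueError("run_mi=False applies only to outcome-missing scenarios")
    # theoretical threshold depends only on (model, pi0); hoisted out of the loop
    threshold = None
    if 0.0 < pi0 < 1.0 and calibration == "theoretical":
        threshold = missingness_threshold(model, pi0)
    r_name = model.role("missingness")
    rows = []
    for rep_ss in seed_sequences[:reps]:
        ss_data, ss_mi = rep_ss.spawn(2)
        if pi0 > 0 and not run_mi:
            # no-imputation path: the large-m MI estimator is the complete-records
            # imputation-model coefficient, so only two OLS fits are needed
            order, mat = _simulate_matrix(model, n_total, ss_data)
            cols = {name: mat[:, i] for i, name in enumerate(order)}
            r = threshold if threshold is not None else float(
                np.quantile(cols[r_name], 1.0 - pi0)
            )
            sel = cols[r_name] <= r
            X_imp = _design(cols, setup["imputation_predictors"], sel)
            beta_imp, _, _ = _ols_core(cols[y][sel], X_imp)
            k = setup["imputation_predictors"].index(x) + 1
            mi_est, mi_se, alpha = float(beta_imp[k]), math.nan, float(beta_imp[k])
            between = 0.0
            X_cra = _design(cols, (x,), sel)
            beta_cra, _, _ = _ols_core(cols[y][sel], X_cra)
            cra = float(beta_cra[1])
            rows.append(
                {"mi": mi_est, "cra": cra, "mi_se_rubin": mi_se, "mi_between_var": between, "alpha_obs": alpha}
            )
            continue
        data = simulate_complete(model, n_total, ss_data)
        if pi0 <= 0:
            if masked == y:
                fit = ols_fit(data, y, setup["imputation_predictors"])
                mi_est, mi_se, alpha = fit.estimate(x), fit.se(x), fit.estimate(x)
            else:
                fit = ols_fit(data, y, [x])
                mi_est, mi_se, alpha = fit.estimate(x), fit.se(x), math.nan
            between = 0.0
            cra = ols_fit(data, y, [x]).estimate(x)
        else:
            spec = (
                MissingnessSpec(masked, threshold=threshold)
                if threshold is not None
                else MissingnessSpec(masked, target_missing_proportion=pi0, calibration=calibration)
            )
            data = impose_missingness(data, spec, model)
            res = mi_analyze(
                data,
                response=y,
                analysis_predictors=(x,),
                imputation_target=masked,
                imputation_predictors=setup["imputation_predictors"],
                m=m,
                seed=np.random.default_rng(ss_mi),
                parameter=x,
            )
            mi_est, mi_se = res.pooled_estimate, res.se
            between = res.between_var
            alpha = res.diagnostics.get("alpha_obs")
            cra = ols_fit(data, y, [x]).estimate(x)
        rows.append(
            {
                "mi": mi_est,
                "cra": cra,
                "mi_se_rubin": mi_se,
                "mi_between_var": between,
                "alpha_obs": math.nan if alpha is None else alpha,
            }
        )
    return pd.DataFrame(rows)


def _large_m_se(est: pd.DataFrame, m: int) -> float:
    """Empirical SE of the MI estimator corrected to the large-m limit.

    Conditional on the data, the pooled estimate is the mean of m independent
    per-imputation estimates, so its variance across replicates exceeds the
    variance of the infinite-m MI estimator by E[B]/m (B the between-
    imputation variance).  Subtracting the mean B/m estimates the SE "given a
    large number of imputations", which is the quantity the analytic SE
    formulas describe.
    """
    v = est["mi"].var(ddof=1) - est["mi_between_var"].mean() / m
    return float(math.sqrt(max(v, 0.0)))


# ---------------------------------------------------------------------------
# Missing-proportion sweep
# ---------------------------------------------------------------------------


def sweep_pi0(
    model: PathModel | str,
    pi0_grid: Sequence[float],
    n_observed: int = 1000,
    reps: int = 500,
    m: int = 20,
    seed: int = 0,
    imputation_predictors: Sequence[str] | None = None,
) -> SweepResult:
    """Bias and SE of the MI-with-collider and CRA estimators along a pi0 grid.

    The number of observed outcome records is held fixed at ``n_observed``.
    Analytic overlays — the maximum-bias bound and the four SE endpoints —
    come from :func:`collidermi.analytic_bias.se_profile` and are independent
    of ``reps`` and ``seed``.
    """
    model = build_path_model(model) if isinstance(model, str) else model
    pi0_grid = list(pi0_grid)
    if any(not (0.0 <= p < 1.0) for p in pi0_grid):
        raise ValueError("pi0 grid must lie in [0, 1)")
    if reps < 2:
        raise ValueError("need at least 2 replicates")
    profile = ab.se_profile(model, n_observed)
    joint = implied_moments(model)
    y, x = model.role("outcome"), model.role("exposure")
    beta_true = conditional_regression(joint, y, [x]).coefficient(x)
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(len(pi0_grid))
    cells = []
    for pi0, cell_ss in zip(pi0_grid, cell_seeds):
        est = replicate_estimates(
            model, pi0, n_observed, reps, m, cell_ss.spawn(reps),
            imputation_predictors=imputation_predictors,
        )
        cells.append(
            {
                "pi0": pi0,
                "n_observed": n_observed,
                "reps": reps,
                "m": m,
                "seed": int(cell_ss.entropy) if isinstance(cell_ss.entropy, int) else seed,
                "beta_true": beta_true,
                "alpha_obs_bias_analytic": (
                    ab.alpha_obs_limit(model, pi0, imputation_predictors).coefficient(x) - beta_true
                    if (imputation_predictors is None or x in imputation_predictors)
                    else math.nan
                ),
                "mi_mean": est["mi"].mean(),
                "mi_bias": est["mi"].mean() - beta_true,
                "mi_se_empirical": est["mi"].std(ddof=1),
                "mi_se_empirical_large_m": _large_m_se(est, m),
                "mi_se_rubin_mean": est["mi_se_rubin"].mean(),
                "cra_mean": est["cra"].mean(),
                "cra_bias": est["cra"].mean() - beta_true,
                "cra_se_empirical": est["cra"].std(ddof=1),
                "max_bias_analytic": profile.max_bias,
                "se_mi_at_0_analytic": profile.se_mi_at_0,
                "se_mi_limit_analytic": profile.se_mi_limit,
                "se_cra_at_0_analytic": profile.se_cra_at_0,
                "se_cra_limit_analytic": profile.se_cra_limit,
            }
        )
    table = pd.DataFrame(cells)
    return SweepResult(table=table, meta={"kind": "pi0_sweep", "seed": seed, "n_observed": n_observed, "reps": reps, "m": m})


# ---------------------------------------------------------------------------
# Effect-size grids
# ---------------------------------------------------------------------------

_FIG1_EDGES = [("R", "X"), ("R", "U"), ("W", "U"), ("Y", "Z"), ("W", "Z")]
_FIG4_EDGES = [("Y", "X"), ("X", "Z"), ("W", "Z"), ("R", "U"), ("W", "U")]
_FIG6_EDGES = [("Y", "X"), ("X", "Z"), ("W", "Z"), ("R", "U"), ("R", "Y"), ("W", "U")]


def sweep_effects(
    scenario: str | PathModel,
    varying: Mapping[tuple[str, str], Sequence[float]] | None = None,
    fixed_pi0: float = 0.5,
    reps: int = 0,
    n_observed: int = 1000,
    m: int = 20,
    seed: int = 0,
) -> SweepResult:
    """Maximum bias / simulated bias over a full factorial grid of path coefficients.

    For outcome-missing (``fig1``) grids the analytic column is the direct
    effect-size maximum-bias formula; for the exposure-missing scenario
    (``fig4``) it is the imputation-coefficient maximum-bias expression; the
    scenario with outcome-driven missingness (``fig6``) has no closed form
    and is simulation-only.  Simulated bias at ``fixed_pi0`` is added to each
    cell when ``reps > 0``.  Box-plot style aggregation over the coefficients
    involving the unmeasured U is available via :func:`aggregate_over`.
    """
    if isinstance(scenario, str):
        name = scenario
        model = build_path_model(scenario)
    else:
        model = scenario
        name = "custom"
    # exposure-driven missingness marks the outcome-missing scenarios (fig1-like);
    # otherwise the exposure is the partially observed variable (fig4/fig6-like)
    r_parents = model.parents.get(model.role("missingness"), ())
    masked_role = "outcome" if model.role("exposure") in r_parents else "exposure"
    # default grids follow the effect-size illustration: 0, 0.25, ..., 1
    default_grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    if varying is None:
        edges = {"fig1": _FIG1_EDGES, "fig4": _FIG4_EDGES, "fig6": _FIG6_EDGES}.get(name)
        if edges is None:
            raise ValueError("explicit 'varying' grids are required for custom scenarios")
        varying = {e: default_grid for e in edges}
    edges = list(varying)
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(reps) if reps else []
    cells = []
    for combo in itertools.product(*(varying[e] for e in edges)):
        updates = dict(zip(edges, combo))
        cell_model = model.with_coefficients(updates)
        row = {f"b_{c}{p}".lower(): v for (c, p), v in updates.items()}
        analytic = math.nan
        if masked_role == "outcome":
            try:
                analytic = ab.max_bias_outcome(cell_model)
            except ab.FormulaDomainError:
                pass
        else:
            try:
                analytic = ab.max_bias_exposure_alpha1(cell_model)
            except ab.FormulaDomainError:
                pass
        row["max_bias_analytic"] = analytic
        row["n_observed"] = n_observed
        row["reps"] = reps
        row["seed"] = seed
        if reps:
            joint = implied_moments(cell_model)
            y, x = cell_model.role("outcome"), cell_model.role("exposure")
            beta_true = conditional_regression(joint, y, [x]).coefficient(x)
            est = replicate_estimates(cell_model, fixed_pi0, n_observed, reps, m, rep_seeds, masked_role=masked_role)
            row["pi0"] = fixed_pi0
            row["beta_true"] = beta_true
            row["sim_bias"] = est["mi"].mean() - beta_true
            row["sim_se_empirical"] = est["mi"].std(ddof=1)
            row["cra_bias"] = est["cra"].mean() - beta_true
        cells.append(row)
    return SweepResult(
        table=pd.DataFrame(cells),
        meta={"kind": "effects_sweep", "scenario": name, "pi0": fixed_pi0, "reps": reps, "m": m, "seed": seed},
    )


def aggregate_over(result: SweepResult, focal: Sequence[str], value: str = "max_bias_analytic") -> pd.DataFrame:
    """Box-plot-ready summary of ``value`` grouped by the focal grid columns.

    Marginalizes (pools) over every non-focal grid axis — e.g. the
    coefficients involving the unmeasured U — returning median, quartiles and
    range per focal cell.
    """
    g = result.table.groupby(list(focal))[value]
    out = g.agg(
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        lo="min",
        hi="max",
        n_cells="count",
    )
    return out.reset_index()


# ---------------------------------------------------------------------------
# SE crossover
# ---------------------------------------------------------------------------


def find_se_crossover(
    model: PathModel | str,
    n_observed: int = 1000,
    reps: int = 500,
    m: int = 20,
    seed: int = 0,
    tol: float = 0.01,
    pi0_grid: Sequence[float] | None = None,
    se_estimator: str = "large_m",
) -> float:
    """Missing proportion at which the MI-with-collider SE first exceeds the CRA SE.

    Empirical SEs are evaluated on a pi0 grid using common random numbers —
    the same replicate seed streams at every grid point — so the SE
    difference curve is smooth in pi0.  The analytic SE results being
    compared are stated for a large number of imputations, where the SE of
    the MI estimator tends to the SE of the complete-records imputation-model
    coefficient; the finite-m imputation-noise floor B/m would otherwise mask
    the crossing entirely.  ``se_estimator`` selects how that large-m SE is
    measured:

    ``"large_m"`` (default)
        standard deviation across replicates of the complete-records
        imputation-model coefficient on the exposure — the exact large-m MI
        estimator, free of imputation noise, so the imputation step is
        skipped and many replicates are affordable;
    ``"pooled"``
        run the m-imputation MI per replicate and correct the variance of
        the pooled estimates by subtracting the mean between-imputation
        variance over m (see :func:`_large_m_se`).

    A quadratic is fitted to the SE difference over the grid and its first
    root located by bracketed root-finding; ``tol`` is the root tolerance.
    Raises if the fitted difference has no sign change on the grid range.
    """
    model = build_path_model(model) if isinstance(model, str) else model
    if se_estimator not in {"large_m", "pooled"}:
        raise ValueError("se_estimator must be 'large_m' or 'pooled'")
    if pi0_grid is None:
        pi0_grid = np.round(np.arange(0.1, 0.85, 0.1), 10)
    pi0_grid = np.asarray(sorted(pi0_grid), dtype=float)
    root_ss = np.random.SeedSequence(seed)
    rep_seeds = root_ss.spawn(reps)  # shared across grid points (common random numbers)
    diffs = np.empty(len(pi0_grid))
    for i, pi0 in enumerate(pi0_grid):
        est = replicate_estimates(
            model, float(pi0), n_observed, reps, m, rep_seeds,
            run_mi=(se_estimator == "pooled"),
        )
        se_mi = _large_m_se(est, m) if se_estimator == "pooled" else est["mi"].std(ddof=1)
        diffs[i] = se_mi - est["cra"].std(ddof=1)
    coefs = np.polyfit(pi0_grid, diffs, 2)
    poly = np.poly1d(coefs)
    lo, hi = float(pi0_grid[0]), float(pi0_grid[-1])
    # first sign change of the fitted curve
    xs = np.linspace(lo, hi, 501)
    vals = poly(xs)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        raise ValueError("no SE crossover of the fitted difference curve on the grid range")
    a, b = xs[sign_change[0]], xs[sign_change[0] + 1]
    return float(optimize.brentq(poly, a, b, xtol=tol))
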
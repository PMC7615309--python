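"""Subject-level data generation: draws from a path model, probit missingness,
latent-normal dichotomization, and the cohort-style synthetic fixture.

Missingness is generated through the latent normal R of the model: the
observed-data indicator is ``R_ind = 1{R <= r}``, so the missing proportion is
``pi0 = P(R > r) = 1 - Phi((r - mu_R) / sqrt(V_R))``.  Under "theoretical"
calibration the threshold ``r`` is set from the implied moments of R, so the
missing proportion is exact in expectation; "empirical" calibration uses the
realized quantile of R, fixing the missing fraction in the sample.

Latent columns (the unmeasured confounder U and the latent R) are retained in
the data table for diagnostics but flagged as latent; estimators take explicit
predictor lists and must never be given them.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sem_core import PathModel, build_path_model, implied_moments, structural_matrices

__all__ = [
    "MissingnessSpec",
    "StudyDataset",
    "simulate_complete",
    "dichotomize",
    "impose_missingness",
    "make_alspac_like",
    "ALSPAC_DEFAULTS",
]


@dataclass(frozen=True)
class MissingnessSpec:
    """How to mask one variable via the latent R.

    Exactly one of ``target_missing_proportion`` (pi0) and ``threshold`` (r)
    is given; with pi0, the threshold is derived according to ``calibration``.
    """

    masked_variable: str
    target_missing_proportion: float | None = None
    threshold: float | None = None
    calibration: str = "theoretical"

    def __post_init__(self) -> None:
        if (self.target_missing_proportion is None) == (self.threshold is None):
            raise ValueError("give exactly one of target_missing_proportion and threshold")
        if self.target_missing_proportion is not None and not (
            0.0 <= self.target_missing_proportion <= 1.0
        ):
            raise ValueError("target missing proportion must lie in [0, 1]")
        if self.calibration not in {"theoretical", "empirical"}:
            raise ValueError("calibration must be 'theoretical' or 'empirical'")


@dataclass
class StudyDataset:
    """A rectangular subject-level table plus provenance metadata.

    ``df`` holds one column per model variable (latent ones included, for
    diagnostics), plus an ``R_ind`` indicator column once missingness has been
    imposed; masked entries of the partially observed column are NaN exactly
    where ``R_ind == 0``.
    """

    df: pd.DataFrame
    latent_columns: tuple[str, ...] = ()
    model: PathModel | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.df)

    def observed_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.latent_columns]

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("dataset must have at least one row")
        if "R_ind" in self.df.columns:
            masked = self.metadata.get("masked_variable")
            if masked is not None:
                r_ind = self.df["R_ind"].to_numpy()
                missing = self.df[masked].isna().to_numpy()
                if not np.array_equal(missing, r_ind == 0):
                    raise ValueError("R_ind = 0 must coincide exactly with masked entries")

    def to_csv(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write the table as CSV (empty field for missing) plus a JSON sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
        if sidecar:
            meta = dict(self.metadata)
            meta["latent_columns"] = list(self.latent_columns)
            meta["n"] = self.n
            path.with_suffix(path.suffix + ".meta.json").write_text(
                json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n"
            )
        return path


def _model_hash(model: PathModel) -> str:
    payload = json.dumps(
        {
            "variables": list(model.variables),
            "parents": {k: list(v) for k, v in sorted(model.parents.items())},
            "coefficients": {f"{c}<-{p}": v for (c, p), v in sorted(model.coefficients.items())},
            "error_variances": dict(sorted(model.error_variances.items())),
            "means": dict(sorted(model.means.items())),
            "roles": dict(sorted(model.roles.items())),
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _variable_stream(seed_sequence: np.random.SeedSequence, name: str) -> np.random.SeedSequence:
    """Child seed stream for one variable, keyed by a stable hash of its name.

    Name-keyed (rather than positional) streams mean that adding or removing a
    downstream variable never perturbs the draws of the others.
    """
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "little")
    return np.random.SeedSequence(
        entropy=seed_sequence.entropy, spawn_key=tuple(seed_sequence.spawn_key) + (key,)
    )


def _simulate_matrix(model: PathModel, n: int, seed_sequence: np.random.SeedSequence) -> tuple[tuple[str, ...], np.ndarray]:
    """Draw n rows from the structural equations; columns in topological order."""
    order, B, nu, d = structural_matrices(model)
    data = np.empty((n, len(order)))
    for i, v in enumerate(order):
        rng = np.random.default_rng(_variable_stream(seed_sequence, v))
        eps = rng.normal(0.0, np.sqrt(d[i]), size=n)
        data[:, i] = nu[i] + data[:, : i] @ B[i, : i] + eps
    return order, data


def simulate_complete(model: PathModel, n: int, seed: int | np.random.SeedSequence) -> StudyDataset:
    """n independent draws from the structural equations of ``model``.

    Every variable equals the linear combination of its parents plus an
    independent Gaussian error; reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    order, data = _simulate_matrix(model, n, ss)
    df = pd.DataFrame(data, columns=list(order))
    latent = tuple(
        model.roles[role] for role in ("unmeasured", "missingness") if role in model.roles
    )
    return StudyDataset(
        df=df,
        latent_columns=latent,
        model=model,
        metadata={
            "seed": getattr(ss, "entropy", None),
            "model_hash": _model_hash(model),
            "n": n,
        },
    )


def dichotomize(data: StudyDataset, variable: str, prevalence: float) -> StudyDataset:
    """Replace a continuous column by an indicator of exceeding a latent threshold.

    The threshold is the theoretical ``1 - prevalence`` quantile of the
    variable's implied marginal normal, so ``P(indicator = 1) = prevalence``
    exactly under the model.  The latent-normal thresholding construction is
    what makes the continuous-case bias results carry over approximately to
    binary variables, provided the prevalence is not close to 0 or 1.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie strictly between 0 and 1")
    if data.model is None:
        raise ValueError("dichotomize requires the generating model for the implied marginal")
    if prevalence < 0.01 or prevalence > 0.99:
        warnings.warn(
            "prevalence is close to 0 or 1; the latent-normal approximation "
            "underlying the binary results degrades in this regime",
            UserWarning,
            stacklevel=2,
        )
    joint = implied_moments(data.model)
    mu = joint.mean_of(variable)
    sd = np.sqrt(joint.var(variable))
    threshold = mu + sd * sps.norm.ppf(1.0 - prevalence)
    df = data.df.copy()
    df[variable] = (df[variable].to_numpy() > threshold).astype(float)
    meta = dict(data.metadata)
    dich = dict(meta.get("dichotomized", {}))
    dich[variable] = {"prevalence": prevalence, "latent_threshold": float(threshold)}
    meta["dichotomized"] = dich
    return replace(data, df=df, metadata=meta)


def missingness_threshold(
    model: PathModel, pi0: float, r_values: np.ndarray | None = None, calibration: str = "theoretical"
) -> float:
    """Threshold r with ``P(R > r) = pi0``.

    Theoretical calibration uses the implied moments of R
    (``r = mu_R + sqrt(V_R) Phi^-1(1 - pi0)``); empirical calibration uses the
    realized ``1 - pi0`` quantile of the supplied draws of R.
    """
    if calibration == "theoretical":
        joint = implied_moments(model)
        r = model.role("missingness")
        return float(joint.mean_of(r) + np.sqrt(joint.var(r)) * sps.norm.ppf(1.0 - pi0))
    if r_values is None:
        raise ValueError("empirical calibration needs the realized draws of R")
    return float(np.quantile(r_values, 1.0 - pi0))


def impose_missingness(
    data: StudyDataset, spec: MissingnessSpec, model: PathModel | None = None
) -> StudyDataset:
    """Mask entries of one variable according to the latent-R probit mechanism.

    Sets ``R_ind = 1`` iff the subject's latent R is at or below the threshold
    and removes masked entries of the target variable where ``R_ind = 0``.
    """
    model = model if model is not None else data.model
    if model is None:
        raise ValueError("impose_missingness requires the generating model")
    if spec.masked_variable not in data.df.columns:
        raise KeyError(f"masked variable {spec.masked_variable!r} not in dataset")
    if data.df[spec.masked_variable].isna().any():
        raise ValueError(f"{spec.masked_variable!r} already has missing entries")
    r_name = model.role("missingness")
    r_values = data.df[r_name].to_numpy()
    if spec.threshold is not None:
        r = float(spec.threshold)
    else:
        pi0 = float(spec.target_missing_proportion)
        if pi0 <= 0.0:
            r = np.inf
        elif pi0 >= 1.0:
            r = -np.inf
        else:
            r = missingness_threshold(model, pi0, r_values, spec.calibration)
    r_ind = (r_values <= r).astype(int)
    df = data.df.copy()
    df["R_ind"] = r_ind
    df.loc[df["R_ind"] == 0, spec.masked_variable] = np.nan
    meta = dict(data.metadata)
    meta["masked_variable"] = spec.masked_variable
    meta["missingness_threshold"] = None if np.isinf(r) else float(r)
    meta["target_missing_proportion"] = spec.target_missing_proportion
    meta["calibration"] = spec.calibration
    out = replace(data, df=df, metadata=meta)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Cohort-style synthetic fixture
# ---------------------------------------------------------------------------

#: Default generating parameters of the synthetic cohort fixture.  Binary
#: exposure ``mated`` (prevalence 0.64, so Var ~ 0.2304) and rare binary direct
#: predictor ``pregsize`` (twin births, prevalence 0.025); continuous collider
#: ``bwt`` in kg with marginal variance ~ 0.286; continuous outcome ``bmi7`` in
#: kg/m^2; latent U standing in for unmeasured family-level factors (e.g.
#: socioeconomic position) that raise birth weight and later BMI and make
#: follow-up more likely; ~40% of the outcome missing (60% observed).  The
#: U -> bmi7 path mirrors the plausible real-data structure under which
#: conditioning on the collider produces a visible attenuation of the exposure
#: coefficient toward the null.
ALSPAC_DEFAULTS: dict[str, float] = {
    "p_mated": 0.64,
    "p_twin": 0.025,
    "bwt_intercept": 3.40,
    "bwt_mated": 0.05,
    "bwt_twin": -0.91,
    "bwt_u": 0.25,
    "bwt_sd": 0.4503,  # total Var(bwt) ~ 0.286
    "bmi_intercept": 16.20,
    "bmi_mated": -0.11,
    "bmi_twin": -0.25,
    "bmi_u": 0.45,
    "bmi_sd": 1.55,
    "r_mated": -0.55,
    "r_u": -0.60,
    "r_sd": 1.0,
    "pi0": 0.40,
}


def make_alspac_like(
    n: int = 12061,
    seed: int | np.random.SeedSequence = 0,
    params: Mapping[str, float] | None = None,
) -> StudyDataset:
    """Synthetic cohort dataset with the M-structure of the applied example.

    Columns: binary exposure ``mated`` (post-16 maternal education), continuous
    outcome ``bmi7`` (child BMI at 7, partially observed), binary direct
    predictor ``pregsize`` (twin birth), continuous collider ``bwt`` (birth
    weight), latent ``U`` and latent ``R`` (flagged latent), and ``R_ind``.
    Binary variables are latent-normal thresholded; missingness of the outcome
    follows the probit mechanism with ~40% missing by default.

    This fixture is synthetic: it emulates the causal structure and headline
    marginals of the real cohort (exposure variance ~0.228, collider variance
    ~0.286, 60% observed outcomes), not its microdata.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    p = dict(ALSPAC_DEFAULTS)
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown fixture parameters: {sorted(unknown)}")
        p.update({k: float(v) for k, v in params.items()})
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(5)]
    mated = (streams[0].random(n) < p["p_mated"]).astype(float)
    pregsize = (streams[1].random(n) < p["p_twin"]).astype(float)
    u = streams[2].standard_normal(n)
    bwt = (
        p["bwt_intercept"]
        + p["bwt_mated"] * mated
        + p["bwt_twin"] * pregsize
        + p["bwt_u"] * u
        + p["bwt_sd"] * streams[3].standard_normal(n)
    )
    bmi7 = (
        p["bmi_intercept"]
        + p["bmi_mated"] * mated
        + p["bmi_twin"] * pregsize
        + p["bmi_u"] * u
        + p["bmi_sd"] * streams[4].standard_normal(n)
    )
    r_rng = np.random.default_rng(ss.spawn(1)[0])
    r = p["r_mated"] * mated + p["r_u"] * u + p["r_sd"] * r_rng.standard_normal(n)
    # theoretical threshold: Var(R) from the generating parameters
    var_r = p["r_mated"] ** 2 * p["p_mated"] * (1 - p["p_mated"]) + p["r_u"] ** 2 + p["r_sd"] ** 2
    mu_r = p["r_mated"] * p["p_mated"]
    threshold = mu_r + np.sqrt(var_r) * sps.norm.ppf(1.0 - p["pi0"])
    r_ind = (r <= threshold).astype(int)
    bmi7 = np.where(r_ind == 1, bmi7, np.nan)
    df = pd.DataFrame(
        {
            "mated": mated,
            "pregsize": pregsize,
            "bwt": bwt,
            "bmi7": bmi7,
            "U": u,
            "R": r,
            "R_ind": r_ind,
        }
    )
    model = build_path_model("fig8-theoretical")
    meta = {
        "seed": getattr(ss, "entropy", None),
        "n": n,
        "masked_variable": "bmi7",
        "missingness_threshold": float(threshold),
        "target_missing_proportion": p["pi0"],
        "calibration": "theoretical",
        "params": p,
        "synthetic": True,
    }
    out = StudyDataset(df=df, latent_columns=("U", "R"), model=model, metadata=meta)
    out.validate()
    return out
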
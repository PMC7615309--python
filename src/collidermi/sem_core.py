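"""Linear-Gaussian path models (DAGs) and their implied moments.

A :class:`PathModel` encodes a directed acyclic graph in which every variable
is a linear combination of its parents plus an independent Gaussian error.
The implied joint distribution of all variables — including unmeasured
confounders and the latent missingness variable R — is multivariate normal
and is computed exactly from the reduced-form linear map from exogenous
errors, so every downstream bias and standard-error formula works with exact
population moments rather than simulated ones.

Named presets encode the M-structure scenarios used throughout the package:

``fig1``
    Outcome Y partially observed. Edges Y<-X, Y<-Z, W<-Z, W<-U, R<-X, R<-U.
    W is a collider of Y (via Z) and missingness (via U).
``fig4``
    Exposure X partially observed, missingness independent of Y.
    Edges Y<-X, X<-Z, W<-Z, W<-U, R<-U.
``fig6``
    As ``fig4`` but the outcome also drives missingness (extra edge R<-Y),
    so complete-records analysis is no longer valid.
``fig8-theoretical``
    The cohort-style relabelling of ``fig1`` (bmi7, mated, pregsize, bwt).

All preset coefficients and error variances default to 1 and means to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "PathModel",
    "JointGaussian",
    "ConditionalModel",
    "build_path_model",
    "implied_moments",
    "conditional_regression",
    "preset_names",
    "ROLES",
]

#: Recognized role labels: which variable plays the outcome Y, exposure X,
#: direct predictor Z, collider W, unmeasured common cause U and the latent
#: missingness variable R.
ROLES = ("outcome", "exposure", "predictor", "collider", "unmeasured", "missingness")

# Relative floor for the smallest eigenvalue of an implied covariance.
_PSD_RTOL = 1e-10


class ModelSpecError(ValueError):
    """Raised for structurally invalid path-model specifications."""


@dataclass(frozen=True)
class PathModel:
    """A linear-Gaussian structural model over named variables.

    Parameters
    ----------
    variables
        Declaration-ordered variable names.
    parents
        Map variable -> tuple of parent names (absent key: no parents).
    coefficients
        Map ``(child, parent)`` -> path coefficient.
    error_variances
        Map variable -> positive error variance.
    means
        Structural intercepts (default 0); the marginal mean of a variable is
        its intercept plus the propagated intercepts of its ancestors.
    roles
        Map role label (see :data:`ROLES`) -> variable name.  The
        ``missingness`` role is mandatory: it names the latent normal R whose
        thresholding defines the observed-data indicator.
    """

    variables: tuple[str, ...]
    parents: Mapping[str, tuple[str, ...]]
    coefficients: Mapping[tuple[str, str], float]
    error_variances: Mapping[str, float]
    means: Mapping[str, float] = field(default_factory=dict)
    roles: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        declared = set(self.variables)
        if len(declared) != len(self.variables):
            raise ModelSpecError("duplicate variable names")
        for child, pars in self.parents.items():
            if child not in declared:
                raise ModelSpecError(f"undeclared child variable {child!r}")
            for p in pars:
                if p not in declared:
                    raise ModelSpecError(f"undeclared parent {p!r} of {child!r}")
        for (child, parent) in self.coefficients:
            if child not in declared or parent not in declared:
                raise ModelSpecError(f"coefficient references undeclared variable: ({child}, {parent})")
            if parent not in self.parents.get(child, ()):
                raise ModelSpecError(f"coefficient for non-edge ({child} <- {parent})")
        for v in self.variables:
            sv = self.error_variances.get(v)
            if sv is None:
                raise ModelSpecError(f"missing error variance for {v!r}")
            if not sv > 0:
                raise ModelSpecError(f"error variance of {v!r} must be > 0, got {sv}")
        for role, v in self.roles.items():
            if role not in ROLES:
                raise ModelSpecError(f"unknown role {role!r}")
            if v not in declared:
                raise ModelSpecError(f"role {role!r} assigned to undeclared variable {v!r}")
        if "missingness" not in self.roles:
            raise ModelSpecError("model must assign the 'missingness' role (latent R)")
        self.topological_order()  # raises on cycles

    # -- graph utilities -------------------------------------------------

    def topological_order(self) -> tuple[str, ...]:
        """Topological order of the DAG; ties broken by declaration order."""
        pars = {v: set(self.parents.get(v, ())) for v in self.variables}
        order: list[str] = []
        remaining = list(self.variables)
        placed: set[str] = set()
        while remaining:
            ready = [v for v in remaining if pars[v] <= placed]
            if not ready:
                raise ModelSpecError(f"cycle detected among {sorted(remaining)}")
            order.append(ready[0])
            placed.add(ready[0])
            remaining.remove(ready[0])
        return tuple(order)

    def coefficient(self, child: str, parent: str, default: float = 0.0) -> float:
        """Path coefficient on the ``child <- parent`` edge (0 if absent)."""
        return float(self.coefficients.get((child, parent), default))

    def mean(self, variable: str) -> float:
        return float(self.means.get(variable, 0.0))

    def role(self, role: str) -> str:
        """Variable name playing ``role``; KeyError if unassigned."""
        return self.roles[role]

    # -- functional updates ---------------------------------------------

    def with_coefficients(self, updates: Mapping[tuple[str, str], float]) -> "PathModel":
        """Copy of the model with some path coefficients replaced.

        Only existing edges may be updated; setting a coefficient to 0 keeps
        the edge (relevant for the zero-factor results).
        """
        coefs = dict(self.coefficients)
        for key, val in updates.items():
            child, parent = key
            if parent not in self.parents.get(child, ()):
                raise ModelSpecError(f"no edge {child} <- {parent} to update")
            coefs[key] = float(val)
        return replace(self, coefficients=coefs)

    def with_error_variances(self, updates: Mapping[str, float]) -> "PathModel":
        ev = dict(self.error_variances)
        ev.update({k: float(v) for k, v in updates.items()})
        return replace(self, error_variances=ev)


@dataclass(frozen=True)
class JointGaussian:
    """Implied joint normal distribution of all model variables."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.names)
        if self.mean.shape != (k,) or self.cov.shape != (k, k):
            raise ValueError("dimension mismatch between names, mean and covariance")
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ValueError("covariance matrix not symmetric")
        eig = np.linalg.eigvalsh(self.cov)
        if eig[0] < -_PSD_RTOL * max(eig[-1], 1.0):
            raise ValueError(f"covariance not positive semi-definite (min eig {eig[0]:g})")

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown variable {name!r}") from None

    def var(self, name: str) -> float:
        i = self.index(name)
        return float(self.cov[i, i])

    def covariance(self, a: str, b: str) -> float:
        return float(self.cov[self.index(a), self.index(b)])

    def mean_of(self, name: str) -> float:
        return float(self.mean[self.index(name)])

    def submatrix(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.index(n) for n in names]
        return self.cov[np.ix_(idx, idx)]

    def conditional_variance(self, target: str, given: Sequence[str]) -> float:
        """Var(target | given) under the joint normal."""
        return conditional_regression(self, target, list(given)).residual_variance

    def conditional_covariance(self, a: str, b: str, given: Sequence[str]) -> float:
        """Cov(a, b | given) under the joint normal."""
        if not given:
            return self.covariance(a, b)
        S = self.submatrix(given)
        ca = np.array([self.covariance(a, g) for g in given])
        cb = np.array([self.covariance(b, g) for g in given])
        return float(self.covariance(a, b) - ca @ np.linalg.solve(S, cb))


@dataclass(frozen=True)
class ConditionalModel:
    """Population linear regression of one variable on a predictor set."""

    target: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: tuple[float, ...]
    residual_variance: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.predictors):
            raise ValueError("coefficient count must equal predictor count")
        if self.residual_variance < -1e-12:
            raise ValueError("negative residual variance")

    def coefficient(self, predictor: str) -> float:
        return self.coefficients[self.predictors.index(predictor)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.predictors, self.coefficients))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _preset_fig1() -> dict:
    return {
        "variables": ["Y", "X", "Z", "W", "U", "R"],
        "edges": [
            ["Y", "X", 1.0],
            ["Y", "Z", 1.0],
            ["W", "Z", 1.0],
            ["W", "U", 1.0],
            ["R", "X", 1.0],
            ["R", "U", 1.0],
        ],
        "error_variances": {v: 1.0 for v in "YXZWUR"},
        "roles": {
            "outcome": "Y",
            "exposure": "X",
            "predictor": "Z",
            "collider": "W",
            "unmeasured": "U",
            "missingness": "R",
        },
    }


def _preset_fig4() -> dict:
    return {
        "variables": ["Y", "X", "Z", "W", "U", "R"],
        "edges": [
            ["Y", "X", 1.0],
            ["X", "Z", 1.0],
            ["W", "Z", 1.0],
            ["W", "U", 1.0],
            ["R", "U", 1.0],
        ],
        "error_variances": {v: 1.0 for v in "YXZWUR"},
        "roles": {
            "outcome": "Y",
            "exposure": "X",
            "predictor": "Z",
            "collider": "W",
            "unmeasured": "U",
            "missingness": "R",
        },
    }


def _preset_fig6() -> dict:
    spec = _preset_fig4()
    spec["edges"].append(["R", "Y", 1.0])
    return spec


def _preset_fig8() -> dict:
    return {
        "variables": ["bmi7", "mated", "pregsize", "bwt", "U", "R"],
        "edges": [
            ["bmi7", "mated", 1.0],
            ["bmi7", "pregsize", 1.0],
            ["bwt", "pregsize", 1.0],
            ["bwt", "U", 1.0],
            ["R", "mated", 1.0],
            ["R", "U", 1.0],
        ],
        "error_variances": {v: 1.0 for v in ["bmi7", "mated", "pregsize", "bwt", "U", "R"]},
        "roles": {
            "outcome": "bmi7",
            "exposure": "mated",
            "predictor": "pregsize",
            "collider": "bwt",
            "unmeasured": "U",
            "missingness": "R",
        },
    }


_PRESETS = {
    "fig1": _preset_fig1,
    "fig4": _preset_fig4,
    "fig6": _preset_fig6,
    "fig8-theoretical": _preset_fig8,
}


def preset_names() -> tuple[str, ...]:
    return tuple(_PRESETS)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def build_path_model(spec: str | Mapping | Path) -> PathModel:
    """Build a validated :class:`PathModel`.

    ``spec`` may be a preset name (``"fig1"``, ``"fig4"``, ``"fig6"``,
    ``"fig8-theoretical"``), a mapping with keys ``variables``, ``edges``
    (list of ``[child, parent, coefficient]``), ``error_variances``, ``means``
    and ``roles``, or a path to a YAML/JSON file holding such a mapping.
    """
    if isinstance(spec, (str, Path)):
        name = str(spec)
        if name in _PRESETS:
            spec = _PRESETS[name]()
        else:
            path = Path(name)
            if not path.exists():
                raise ModelSpecError(f"unknown preset or missing file: {name!r}")
            text = path.read_text()
            if path.suffix.lower() in {".yaml", ".yml"}:
                import yaml

                spec = yaml.safe_load(text)
            else:
                spec = json.loads(text)
    if not isinstance(spec, Mapping):
        raise ModelSpecError("scenario spec must be a mapping or preset name")

    variables = tuple(spec["variables"])
    parents: dict[str, tuple[str, ...]] = {v: () for v in variables}
    coefficients: dict[tuple[str, str], float] = {}
    for edge in spec.get("edges", []):
        child, parent, coef = edge[0], edge[1], float(edge[2]) if len(edge) > 2 else 1.0
        if child == parent:
            raise ModelSpecError(f"self-loop on {child!r}")
        if child not in parents:
            raise ModelSpecError(f"undeclared child variable {child!r}")
        parents[child] = parents[child] + (parent,)
        coefficients[(child, parent)] = coef
    return PathModel(
        variables=variables,
        parents=parents,
        coefficients=coefficients,
        error_variances={k: float(v) for k, v in dict(spec.get("error_variances", {})).items()},
        means={k: float(v) for k, v in dict(spec.get("means", {})).items()},
        roles=dict(spec.get("roles", {})),
    )


# ---------------------------------------------------------------------------
# Moments
# ---------------------------------------------------------------------------


def structural_matrices(model: PathModel) -> tuple[tuple[str, ...], np.ndarray, np.ndarray, np.ndarray]:
    """Topological names, coefficient matrix B, intercepts nu, error variances d.

    In topological order the structural equations are ``v = nu + B v + e`` with
    B strictly lower-triangular, so the reduced form is ``v = T(nu + e)`` with
    ``T = (I - B)^{-1}``.
    """
    order = model.topological_order()
    k = len(order)
    B = np.zeros((k, k))
    for i, child in enumerate(order):
        for parent in model.parents.get(child, ()):
            B[i, order.index(parent)] = model.coefficient(child, parent)
    nu = np.array([model.mean(v) for v in order])
    d = np.array([float(model.error_variances[v]) for v in order])
    return order, B, nu, d


def implied_moments(model: PathModel) -> JointGaussian:
    """Exact implied mean vector and covariance matrix of all variables.

    Uses the reduced-form map from exogenous errors: with ``T = (I - B)^{-1}``,
    the mean is ``T nu`` and the covariance is ``T diag(sigma^2) T'``.
    """
    order, B, nu, d = structural_matrices(model)
    T = np.linalg.inv(np.eye(len(order)) - B)
    mean = T @ nu
    cov = T @ np.diag(d) @ T.T
    cov = (cov + cov.T) / 2.0  # enforce exact symmetry
    return JointGaussian(names=order, mean=mean, cov=cov)


def conditional_regression(
    joint: JointGaussian, target: str, predictors: Sequence[str]
) -> ConditionalModel:
    """Population least-squares regression of ``target`` on ``predictors``.

    Coefficients solve the normal equations ``Sigma_pp b = sigma_pt`` built
    from the joint covariance; the residual variance is the Gaussian
    conditional variance ``Var(target) - sigma_tp' b``.
    """
    predictors = list(predictors)
    if target in predictors:
        raise ValueError("target cannot be one of its own predictors")
    t_var = joint.var(target)
    t_mean = joint.mean_of(target)
    if not predictors:
        return ConditionalModel(target, (), t_mean, (), t_var)
    S = joint.submatrix(predictors)
    c = np.array([joint.covariance(target, p) for p in predictors])
    # reject collinear predictor sets rather than returning a pseudo-inverse fit
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(f"singular predictor covariance for {predictors}")
    b = np.linalg.solve(S, c)
    resid = float(t_var - c @ b)
    resid = max(resid, 0.0)
    mu_p = np.array([joint.mean_of(p) for p in predictors])
    intercept = float(t_mean - b @ mu_p)
    return ConditionalModel(target, tuple(predictors), intercept, tuple(float(x) for x in b), resid)
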
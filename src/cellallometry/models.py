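"""The four Bayesian regression models of cell-type allometry.

All models describe the log10 cell-type number ``k`` as normally
distributed around a regression curve of the log10 cell number ``n``
(everything is fit in double log-space):

mean functions
    * ``double_power_law`` — piecewise linear in (n, k) with a breakpoint:
      two power-law regimes for small and large organisms.
    * ``diminishing_returns`` — ``f(n) = log10(A + B * n)``, the closed
      form of the fitness model in :mod:`cellallometry.fitness`.

noise models
    * ``constant`` — a single standard deviation ``Sigma``.
    * ``variable`` — ``g(n) = Sigma0 + s_Sigma * n``, the spread of ``k``
      increasing linearly with log cell number.

Priors (fixed by the model definitions)::

    k0      ~ Uniform(-0.5, 0.5)
    s_small, s_large, A, B ~ Normal(0, 20)
    n_bp    ~ Normal(5, 2)
    Sigma   ~ HalfCauchy(scale=10)
    Sigma0, s_Sigma ~ HalfNormal(sd=1)

Regression variables are base-10 logs; all probability densities are in
natural log, so log likelihoods and elpd values are in conventional nats.
Parameter points outside the model's domain (``A + B*n <= 0`` anywhere in
the data, non-positive standard deviation at a data point) get log
probability ``-inf`` rather than raising, so samplers can simply reject
them — equivalent to truncating the prior to the valid region.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Mapping, Union

import numpy as np
from scipy import stats

from .data import AllometryDataset

__all__ = [
    "ModelSpec",
    "DoublePowerLawParams",
    "DiminishingReturnsParams",
    "ConstantNoise",
    "VariableNoise",
    "MODEL_NAMES",
    "PRIORS",
    "mean_double_power_law",
    "mean_diminishing_returns",
    "sd_function",
    "mean_function",
    "pointwise_log_likelihood",
    "log_prior",
    "log_posterior",
    "params_to_json",
    "params_from_json",
]

_LOG_2PI = math.log(2.0 * math.pi)

MEAN_KINDS = ("double_power_law", "diminishing_returns")
SD_KINDS = ("constant", "variable")

_MEAN_PARAMS = {
    "double_power_law": ("k0", "s_small", "n_bp", "s_large"),
    "diminishing_returns": ("A", "B"),
}
_SD_PARAMS = {
    "constant": ("Sigma",),
    "variable": ("Sigma0", "s_Sigma"),
}

# Short model names used throughout the CLI and outputs.
_NAME_OF = {
    ("double_power_law", "constant"): "dpl_const",
    ("double_power_law", "variable"): "dpl_var",
    ("diminishing_returns", "constant"): "dr_const",
    ("diminishing_returns", "variable"): "dr_var",
}
MODEL_NAMES = tuple(_NAME_OF.values())

#: Prior distribution per parameter symbol (scipy frozen distributions;
#: half distributions are already normalized on the positive half-line).
PRIORS = {
    "k0": stats.uniform(loc=-0.5, scale=1.0),
    "s_small": stats.norm(0.0, 20.0),
    "s_large": stats.norm(0.0, 20.0),
    "A": stats.norm(0.0, 20.0),
    "B": stats.norm(0.0, 20.0),
    "n_bp": stats.norm(5.0, 2.0),
    "Sigma": stats.halfcauchy(scale=10.0),
    "Sigma0": stats.halfnorm(scale=1.0),
    "s_Sigma": stats.halfnorm(scale=1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four regression models: a mean kind plus a noise kind."""

    mean_kind: str = "diminishing_returns"
    sd_kind: str = "constant"

    def __post_init__(self) -> None:
        if self.mean_kind not in MEAN_KINDS:
            raise ValueError(f"unknown mean_kind {self.mean_kind!r}")
        if self.sd_kind not in SD_KINDS:
            raise ValueError(f"unknown sd_kind {self.sd_kind!r}")

    @property
    def name(self) -> str:
        return _NAME_OF[(self.mean_kind, self.sd_kind)]

    @property
    def mean_param_names(self) -> tuple[str, ...]:
        return _MEAN_PARAMS[self.mean_kind]

    @property
    def sd_param_names(self) -> tuple[str, ...]:
        return _SD_PARAMS[self.sd_kind]

    @property
    def param_names(self) -> tuple[str, ...]:
        return self.mean_param_names + self.sd_param_names

    @property
    def ndim(self) -> int:
        return len(self.param_names)

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        for (mean_kind, sd_kind), short in _NAME_OF.items():
            if short == name:
                return cls(mean_kind=mean_kind, sd_kind=sd_kind)
        raise ValueError(
            f"unknown model name {name!r}; expected one of {MODEL_NAMES}"
        )

    def label(self) -> str:
        mean = {
            "double_power_law": "Double power law",
            "diminishing_returns": "Diminishing returns",
        }[self.mean_kind]
        sd = {"constant": "constant sd", "variable": "variable sd"}[self.sd_kind]
        return f"{mean}, {sd}"


@dataclass(frozen=True)
class DoublePowerLawParams:
    k0: float
    s_small: float
    n_bp: float
    s_large: float


@dataclass(frozen=True)
class DiminishingReturnsParams:
    A: float
    B: float


@dataclass(frozen=True)
class ConstantNoise:
    Sigma: float


@dataclass(frozen=True)
class VariableNoise:
    Sigma0: float
    s_Sigma: float


ParamsLike = Union[Mapping[str, float], object]


def _as_mapping(params: ParamsLike) -> Mapping[str, float]:
    if isinstance(params, Mapping):
        return params
    return asdict(params)


def params_to_json(params: ParamsLike) -> str:
    """Serialize a parameter point to a flat JSON object keyed by symbol."""
    return json.dumps({k: float(v) for k, v in _as_mapping(params).items()})


def params_from_json(s: str) -> dict[str, float]:
    return {k: float(v) for k, v in json.loads(s).items()}


# ---------------------------------------------------------------------------
# mean and sd functions (scalar or broadcastable array inputs)


def mean_double_power_law(n, params: ParamsLike):
    """Piecewise linear mean: slope s_small below the breakpoint n_bp,
    s_large at and above it; continuous at n_bp by construction."""
    p = _as_mapping(params)
    n = np.asarray(n, dtype=float)
    k0, s_small = p["k0"], p["s_small"]
    n_bp, s_large = p["n_bp"], p["s_large"]
    out = np.where(
        n < n_bp,
        k0 + np.multiply(s_small, n),
        k0 + np.multiply(s_small, n_bp) + np.multiply(s_large, n - n_bp),
    )
    return out if out.ndim else float(out)


def mean_diminishing_returns(n, params: ParamsLike):
    """Capacity mean f(n) = log10(A + B*n); NaN where A + B*n <= 0.

    The NaN marks a domain violation; the likelihood maps it to log
    probability -inf instead of raising.
    """
    p = _as_mapping(params)
    n = np.asarray(n, dtype=float)
    arg = p["A"] + np.multiply(p["B"], n)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(arg > 0, np.log10(np.where(arg > 0, arg, 1.0)), np.nan)
    return out if out.ndim else float(out)


def mean_function(n, spec: ModelSpec, params: ParamsLike):
    if spec.mean_kind == "double_power_law":
        return mean_double_power_law(n, params)
    return mean_diminishing_returns(n, params)


def sd_function(n, noise: ParamsLike):
    """Standard deviation of k at n: constant Sigma, or Sigma0 + s_Sigma*n.

    The variant is inferred from the keys present.  Non-positive values are
    returned as-is; the likelihood treats them as domain violations.
    """
    p = _as_mapping(noise)
    n = np.asarray(n, dtype=float)
    if "Sigma" in p:
        out = np.broadcast_to(np.asarray(p["Sigma"], dtype=float), n.shape).copy() \
            if n.ndim else np.asarray(p["Sigma"], dtype=float)
        return out if np.ndim(out) else float(out)
    out = p["Sigma0"] + np.multiply(p["s_Sigma"], n)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# likelihood, prior, posterior


def _theta_from_params(spec: ModelSpec, params: ParamsLike) -> np.ndarray:
    p = _as_mapping(params)
    missing = [name for name in spec.param_names if name not in p]
    if missing:
        raise ValueError(f"parameter point missing {missing} for {spec.name}")
    return np.array([float(p[name]) for name in spec.param_names])


def _mean_sd_from_theta(spec: ModelSpec, n: np.ndarray, theta: np.ndarray):
    """Vectorized mean and sd: theta (..., ndim) -> (mu, sd) of shape (..., n_obs)."""
    names = spec.param_names
    cols = {name: theta[..., i, None] for i, name in enumerate(names)}
    if spec.mean_kind == "double_power_law":
        mu = np.where(
            n < cols["n_bp"],
            cols["k0"] + cols["s_small"] * n,
            cols["k0"] + cols["s_small"] * cols["n_bp"]
            + cols["s_large"] * (n - cols["n_bp"]),
        )
    else:
        arg = cols["A"] + cols["B"] * n
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(arg > 0, np.log10(np.where(arg > 0, arg, 1.0)), np.nan)
    if spec.sd_kind == "constant":
        sd = np.broadcast_to(cols["Sigma"], mu.shape)
    else:
        sd = np.broadcast_to(cols["Sigma0"] + cols["s_Sigma"] * n, mu.shape)
    return mu, sd


def loglik_matrix(
    dataset: AllometryDataset, spec: ModelSpec, theta: np.ndarray
) -> np.ndarray:
    """Pointwise normal log densities for a batch of parameter vectors.

    theta has shape (..., ndim) ordered as ``spec.param_names``; the result
    has shape (..., n_obs) in natural log, with -inf marking domain
    violations (invalid mean or non-positive sd).
    """
    theta = np.asarray(theta, dtype=float)
    n, k = dataset.n, dataset.k
    mu, sd = _mean_sd_from_theta(spec, n, theta)
    valid = np.isfinite(mu) & (sd > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (k - mu) / sd
        ll = -0.5 * _LOG_2PI - np.log(sd) - 0.5 * z * z
    return np.where(valid, ll, -np.inf)


def pointwise_log_likelihood(
    dataset: AllometryDataset, spec: ModelSpec, params: ParamsLike
) -> np.ndarray:
    """Vector of per-observation normal log densities (natural log).

    Element i is log Normal(k_i | f(n_i), sigma(n_i)); the sum is the total
    log likelihood.  Domain violations yield -inf elements.
    """
    if dataset.n_obs == 0:
        raise ValueError("dataset is empty")
    theta = _theta_from_params(spec, params)
    return loglik_matrix(dataset, spec, theta)


def log_prior_vec(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    """Sum of independent log prior densities for theta of shape (..., ndim)."""
    theta = np.asarray(theta, dtype=float)
    out = np.zeros(theta.shape[:-1])
    for i, name in enumerate(spec.param_names):
        with np.errstate(invalid="ignore", divide="ignore"):
            out = out + PRIORS[name].logpdf(theta[..., i])
    return np.where(np.isnan(out), -np.inf, out)


def log_prior(spec: ModelSpec, params: ParamsLike) -> float:
    """Scalar log prior density; -inf outside the support."""
    theta = _theta_from_params(spec, params)
    return float(log_prior_vec(spec, theta))


def log_posterior(
    dataset: AllometryDataset, spec: ModelSpec, params: ParamsLike
) -> float:
    """Unnormalized log posterior: total log likelihood plus log prior."""
    lp = log_prior(spec, params)
    if not np.isfinite(lp):
        return -np.inf
    ll = float(np.sum(pointwise_log_likelihood(dataset, spec, params)))
    return lp + ll


def log_posterior_vec(
    dataset: AllometryDataset, spec: ModelSpec, theta: np.ndarray
) -> np.ndarray:
    """Batched unnormalized log posterior for theta of shape (..., ndim)."""
    theta = np.asarray(theta, dtype=float)
    lp = log_prior_vec(spec, theta)
    if dataset.n_obs:
        ll = loglik_matrix(dataset, spec, theta).sum(axis=-1)
        with np.errstate(invalid="ignore"):
            out = np.where(np.isfinite(lp), lp + ll, -np.inf)
        return np.where(np.isnan(out), -np.inf, out)
    return lp
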
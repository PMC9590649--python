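"""Evolutionary cost/benefit model of cell-type segregation events.

The appearance of a new cell type is treated as a discrete evolutionary
event (functional segregation of a multifunctional ancestor into sister
types).  The event carries a fitness cost that scales as a power law with
total cell number ``N`` and a fitness benefit that also scales as a power
law with ``N`` but is reduced by a constant factor ``b > 1`` for every cell
type that already exists::

    delta_f = a * N**gamma * b**(-K) - c * N**delta

Requiring a non-negative net fitness change for a new type to appear yields
a closed-form capacity, linear in log10 cell number::

    K = A + B * log10(N),   A = log10(a/c) / log10(b),
                            B = (gamma - delta) / log10(b)

so the log cell-type number follows ``k = log10(A + B * n)`` — a curve
that is *not* a power law in ``N``.  A discrete forward simulator of
successive accept/reject segregation events is provided as an internal
consistency oracle for the closed form.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Union

import numpy as np

__all__ = [
    "FitnessParams",
    "ClosedFormCoefficients",
    "delta_fitness",
    "fitness_benefit",
    "fitness_cost",
    "closed_form_coefficients",
    "capacity",
    "simulate_accumulation",
    "AccumulationResult",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class FitnessParams:
    """Mechanistic parameters of the cost/benefit model.

    Parameters
    ----------
    a : float
        Benefit amplitude, > 0.
    b : float
        Per-event benefit decay factor, > 1: each existing cell type
        reduces the benefit of the next segregation event by 1/b.
    c : float
        Cost amplitude, > 0.
    gamma : float
        Exponent of the benefit power law in cell number.
    delta : float
        Exponent of the cost power law in cell number.
    """

    a: float
    b: float
    c: float
    gamma: float
    delta: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "gamma", "delta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.a <= 0:
            raise ValueError(f"benefit amplitude a must be > 0, got {self.a}")
        if self.c <= 0:
            raise ValueError(f"cost amplitude c must be > 0, got {self.c}")
        if self.b <= 1:
            raise ValueError(
                f"benefit decay factor b must be > 1, got {self.b}"
            )
        if self.gamma <= self.delta:
            warnings.warn(
                "gamma <= delta: cell-type capacity does not increase with "
                "cell number under these parameters",
                UserWarning,
                stacklevel=2,
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "FitnessParams":
        return cls(**json.loads(s))


@dataclass(frozen=True)
class ClosedFormCoefficients:
    """Intercept ``A`` and slope ``B`` of cell-type capacity vs log10 N."""

    A: float
    B: float


def _check_N(N: ArrayLike) -> np.ndarray:
    N = np.asarray(N, dtype=float)
    if not np.all(np.isfinite(N)) or np.any(N <= 0):
        raise ValueError("cell number N must be finite and > 0")
    return N


def fitness_benefit(N: ArrayLike, K: ArrayLike, params: FitnessParams) -> ArrayLike:
    """Benefit term a * N**gamma * b**(-K) of the next segregation event.

    ``K`` is the number of *existing* cell types before the event.
    """
    N = _check_N(N)
    K = np.asarray(K, dtype=float)
    out = params.a * N**params.gamma * params.b ** (-K)
    return out if out.ndim else float(out)


def fitness_cost(N: ArrayLike, params: FitnessParams) -> ArrayLike:
    """Cost term c * N**delta of a segregation event."""
    N = _check_N(N)
    out = params.c * N**params.delta
    return out if out.ndim else float(out)


def delta_fitness(N: ArrayLike, K: ArrayLike, params: FitnessParams) -> ArrayLike:
    """Net fitness change of adding one cell type to an organism.

    delta_f(N, K) = a * N**gamma * b**(-K) - c * N**delta, strictly
    decreasing in K for fixed N.  Accepts scalars or broadcastable arrays.
    """
    return fitness_benefit(N, K, params) - fitness_cost(N, params)


def closed_form_coefficients(params: FitnessParams) -> ClosedFormCoefficients:
    """Coefficients (A, B) of the capacity line K = A + B * log10(N).

    Solving delta_fitness = 0 for K gives
    A = log10(a/c) / log10(b) and B = (gamma - delta) / log10(b).
    """
    log10b = math.log10(params.b)
    A = math.log10(params.a / params.c) / log10b
    B = (params.gamma - params.delta) / log10b
    return ClosedFormCoefficients(A=A, B=B)


def capacity(N: ArrayLike, coeffs: ClosedFormCoefficients) -> ArrayLike:
    """Real-valued cell-type capacity A + B * log10(N).

    May be negative for tiny N; callers decide how to interpret values
    below one (display code floors at 1, likelihood code never does).
    """
    N = _check_N(N)
    out = coeffs.A + coeffs.B * np.log10(N)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class AccumulationResult:
    """Outcome of a forward accumulation simulation."""

    K: int
    capped: bool


def simulate_accumulation(
    N: float, params: FitnessParams, k_max: int = 10_000
) -> AccumulationResult:
    """Discrete forward simulation of successive segregation events.

    Starting from a single ancestral type (K = 1), the transition
    K -> K + 1 is accepted while delta_fitness(N, K) >= 0, with the
    benefit evaluated at the current (pre-event) number of types; the
    boundary case delta_f = 0 is accepted, matching the equality solved
    by the closed form.  Stops at the first rejected event or at
    ``k_max`` (flagged via ``capped``).
    """
    N = float(N)
    if not math.isfinite(N) or N <= 0:
        raise ValueError("cell number N must be finite and > 0")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    K = 1
    while K < k_max:
        if delta_fitness(N, K, params) < 0:
            return AccumulationResult(K=K, capped=False)
        K += 1
    return AccumulationResult(K=K, capped=True)
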
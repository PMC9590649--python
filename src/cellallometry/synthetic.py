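"""Synthetic allometry datasets with the structure the analysis assumes.

The generator runs the regression models forwards: log10 cell numbers
``n`` are drawn over a range spanning roughly fourteen decades (bacteria
to blue whale), log10 cell-type numbers ``k`` are drawn from
Normal(f(n), sigma(n)), and the counts N = 10^n, K = 10^k must satisfy
1 <= K <= N.  Records violating the constraint are redrawn in full (not
clipped, which would distort the noise model the fitters assume).

``fisher_like_profile`` provides defaults that emulate the published
survey of cell type counts across organisms: 60 organisms, diminishing-
returns truth with capacity intercept A = -0.29, slope B = 1.29 and
constant observation noise Sigma = 0.33 in log10 units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .data import AllometryDataset
from .models import ModelSpec, mean_function, sd_function

__all__ = ["GeneratorConfig", "generate_dataset", "fisher_like_profile"]

_MAX_ATTEMPTS = 100


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic-data generator.

    ``n_distribution`` is "uniform" (n ~ Uniform over ``n_range``) or
    "resample" (n drawn with replacement from ``n_values``, e.g. the
    design of a real dataset).
    """

    spec: ModelSpec
    params: dict[str, float]
    size: int = 60
    n_range: tuple[float, float] = (0.3, 14.0)
    n_distribution: str = "uniform"
    n_values: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("size must be >= 2")
        lo, hi = self.n_range
        if not lo < hi:
            raise ValueError("n_range lower bound must be below upper bound")
        if self.n_distribution not in ("uniform", "resample"):
            raise ValueError(
                f"unknown n_distribution {self.n_distribution!r}"
            )
        if self.n_distribution == "resample" and self.n_values is None:
            raise ValueError("n_values required for resample distribution")
        missing = [p for p in self.spec.param_names if p not in self.params]
        if missing:
            raise ValueError(f"params missing {missing} for {self.spec.name}")
        ends = np.array([lo, hi])
        mu = mean_function(ends, self.spec, self.params)
        if not np.all(np.isfinite(mu)):
            raise ValueError(
                "mean function undefined over n_range "
                "(diminishing-returns capacity A + B*n <= 0)"
            )
        sd = np.asarray(sd_function(ends, self.params), dtype=float)
        if np.any(sd < 0):
            raise ValueError("noise sd is negative somewhere over n_range")

    def to_json(self) -> str:
        d = asdict(self)
        d["spec"] = {"mean_kind": self.spec.mean_kind, "sd_kind": self.spec.sd_kind}
        if self.n_values is not None:
            d["n_values"] = np.asarray(self.n_values).tolist()
        d["n_range"] = list(self.n_range)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "GeneratorConfig":
        d = json.loads(s)
        d["spec"] = ModelSpec(**d["spec"])
        if d.get("n_values") is not None:
            d["n_values"] = np.asarray(d["n_values"], dtype=float)
        d["n_range"] = tuple(d["n_range"])
        return cls(**d)


def generate_dataset(config: GeneratorConfig) -> AllometryDataset:
    """Draw a dataset from the generating model, enforcing 1 <= K <= N.

    Per record up to 100 (n, k) proposals are drawn; a proposal is
    accepted when 0 <= k <= n.  Deterministic given the seed.
    """
    rng = np.random.default_rng(int(config.seed) % (2**31))
    lo, hi = config.n_range
    n_out = np.empty(config.size)
    k_out = np.empty(config.size)
    for i in range(config.size):
        for attempt in range(_MAX_ATTEMPTS):
            if config.n_distribution == "uniform":
                n = rng.uniform(lo, hi)
            else:
                n = float(rng.choice(np.asarray(config.n_values, dtype=float)))
            mu = float(mean_function(n, config.spec, config.params))
            sd = float(sd_function(n, config.params))
            k = mu if sd == 0 else rng.normal(mu, sd)
            if np.isfinite(k) and 0.0 <= k <= n:
                n_out[i], k_out[i] = n, k
                break
        else:
            raise ValueError(
                f"could not draw record {i} satisfying 1 <= K <= N within "
                f"{_MAX_ATTEMPTS} attempts; check params against n_range"
            )
    labels = [f"synthetic_{i:03d}" for i in range(config.size)]
    return AllometryDataset(N=10.0**n_out, K=10.0**k_out, labels=labels)


def fisher_like_profile(size: int = 60, seed: int = 0) -> GeneratorConfig:
    """Ready-made profile emulating the published cell-type survey.

    Diminishing-returns mean with A = -0.29, B = 1.29, constant noise
    Sigma = 0.33, 60 organisms spanning log10 cell numbers 0.3-14.
    """
    return GeneratorConfig(
        spec=ModelSpec("diminishing_returns", "constant"),
        params={"A": -0.29, "B": 1.29, "Sigma": 0.33},
        size=size,
        n_range=(0.3, 14.0),
        n_distribution="uniform",
        seed=seed,
    )
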
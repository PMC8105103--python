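"""Synthetic growth-curve generation for fitting tests and demos.

``generate_fixture`` evaluates a growth model's closed form at the requested
times and perturbs it with multiplicative log-normal noise:

    V_obs(t) = V(t) * exp(sigma * Z),   Z ~ N(0, 1) i.i.d.

so ``sigma`` is approximately the coefficient of variation (sigma = 0.1 is
~10% measurement noise) and the noiseless curve is the median.  A fixed seed
makes the output bit-for-bit reproducible; the simulator itself contains no
randomness — seeds live only here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .growth import (
    GompertzParams,
    GrowthCurve,
    LogisticParams,
    gompertz_solution,
    logistic_solution,
)

__all__ = ["FixtureSpec", "generate_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic noisy growth curve."""

    model: str  # "logistic" | "gompertz"
    params: LogisticParams | GompertzParams
    v0: float
    times: tuple
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("logistic", "gompertz"):
            raise InputError(f"unknown fixture model {self.model!r}")
        if self.sigma < 0:
            raise InputError(f"noise sigma must be >= 0, got {self.sigma}")
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))


def generate_fixture(spec: FixtureSpec) -> GrowthCurve:
    """Closed-form curve times log-normal noise; same seed, same bytes."""
    t = np.asarray(spec.times)
    if spec.model == "logistic":
        v = logistic_solution(spec.params, spec.v0, t)
    else:
        v = gompertz_solution(spec.params, spec.v0, t)
    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        v = v * np.exp(spec.sigma * rng.standard_normal(v.shape))
    return GrowthCurve(times=t, volumes=v)
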
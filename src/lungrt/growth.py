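"""Single-population baseline tumor-growth models.

Two classical volume-growth laws for untreated tumors, each with a
closed-form solution and an ODE route through :func:`scipy.integrate.solve_ivp`:

* logistic:  dV/dt = a V (1 - V/K), saturating at the carrying capacity K;
* Gompertz:  dV/dt = a V - b V ln V, saturating at exp(a/b).

Volumes are in mm^3 and times in days throughout.  Default parameter values
are fits to NSCLC (A549 xenograft) growth data:
``DEFAULT_LOGISTIC`` (a = 0.502 / day, K = 1297 mm^3) and
``DEFAULT_GOMPERTZ`` (a = 0.743 / day, b = 0.0792 / day).

A least-squares fitter recovers model parameters from observed time-volume
curves and reports the residual sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import InputError, SimulationError

__all__ = [
    "LogisticParams",
    "GompertzParams",
    "GrowthCurve",
    "FitResult",
    "DEFAULT_LOGISTIC",
    "DEFAULT_GOMPERTZ",
    "logistic_solution",
    "gompertz_solution",
    "simulate_logistic",
    "simulate_gompertz",
    "fit_growth_curve",
    "save_growth_params",
    "load_growth_params",
]

# Solver tolerances tight enough that closed-form solutions act as exact
# oracles in tests (relative deviation < 1e-6 over 100 days).
RTOL = 1e-8
ATOL = 1e-10
_ODE_METHOD = "DOP853"


@dataclass(frozen=True)
class LogisticParams:
    """Logistic growth parameters.

    Attributes
    ----------
    a : float
        Proliferation rate, per day.  Must be positive.
    K : float
        Carrying capacity, mm^3.  Must be positive.
    """

    a: float
    K: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise InputError(f"logistic rate a must be > 0, got {self.a}")
        if not self.K > 0:
            raise InputError(f"carrying capacity K must be > 0, got {self.K}")


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz growth parameters.

    Attributes
    ----------
    a : float
        Growth coefficient, per day.  Must be positive.
    b : float
        Deceleration coefficient, per day.  Must be positive.
        The asymptotic volume is exp(a/b) mm^3.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise InputError(f"Gompertz coefficient a must be > 0, got {self.a}")
        if not self.b > 0:
            raise InputError(f"Gompertz coefficient b must be > 0, got {self.b}")

    @property
    def plateau(self) -> float:
        """Asymptotic volume exp(a/b), mm^3."""
        return float(np.exp(self.a / self.b))


DEFAULT_LOGISTIC = LogisticParams(a=0.502, K=1297.0)
DEFAULT_GOMPERTZ = GompertzParams(a=0.743, b=0.0792)


def _validate_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputError("times must be a non-empty 1-D sequence")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InputError("times must be strictly increasing")
    return t


@dataclass
class GrowthCurve:
    """A sampled volume trajectory V(t).

    times are days (strictly increasing), volumes are mm^3 (non-negative),
    same length.
    """

    times: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.times = _validate_times(self.times)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.volumes.shape != self.times.shape:
            raise InputError(
                f"times and volumes length mismatch: {self.times.size} vs {self.volumes.size}"
            )
        if np.any(self.volumes < 0):
            raise InputError("volumes must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_days": self.times, "volume_mm3": self.volumes})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "GrowthCurve":
        df = pd.read_csv(path)
        missing = {"time_days", "volume_mm3"} - set(df.columns)
        if missing:
            raise InputError(f"growth-curve CSV missing columns: {sorted(missing)}")
        return cls(df["time_days"].to_numpy(), df["volume_mm3"].to_numpy())


def logistic_solution(params: LogisticParams, v0: float, times) -> np.ndarray:
    """Closed-form logistic solution V(t) = K / (1 + (K/v0 - 1) e^{-a t}).

    Times are measured from the first entry of ``times``; ``v0`` is the
    volume there.  ``v0 = 0`` returns identically zero (the unstable
    equilibrium).
    """
    t = _validate_times(times)
    if v0 < 0:
        raise InputError(f"initial volume must be >= 0, got {v0}")
    if v0 == 0:
        return np.zeros_like(t)
    tau = t - t[0]
    return params.K / (1.0 + (params.K / v0 - 1.0) * np.exp(-params.a * tau))


def gompertz_solution(params: GompertzParams, v0: float, times) -> np.ndarray:
    """Closed-form Gompertz solution V(t) = exp(a/b + (ln v0 - a/b) e^{-b t})."""
    t = _validate_times(times)
    if v0 <= 0:
        raise InputError(f"Gompertz requires initial volume > 0 (ln V), got {v0}")
    tau = t - t[0]
    ab = params.a / params.b
    return np.exp(ab + (np.log(v0) - ab) * np.exp(-params.b * tau))


def _integrate_scalar(rhs, v0: float, times: np.ndarray) -> np.ndarray:
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        [v0],
        t_eval=times,
        method=_ODE_METHOD,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise SimulationError(f"growth ODE solver failed: {sol.message}", last_time=last)
    return sol.y[0]


def simulate_logistic(params: LogisticParams, v0: float, times) -> GrowthCurve:
    """Integrate logistic growth dV/dt = a V (1 - V/K) at the requested times."""
    t = _validate_times(times)
    if v0 < 0:
        raise InputError(f"initial volume must be >= 0, got {v0}")
    if t.size == 1:
        return GrowthCurve(t, np.array([v0]))

    def rhs(_t, y):
        return params.a * y * (1.0 - y / params.K)

    v = _integrate_scalar(rhs, v0, t)
    return GrowthCurve(t, np.clip(v, 0.0, None))


def simulate_gompertz(params: GompertzParams, v0: float, times) -> GrowthCurve:
    """Integrate Gompertz growth dV/dt = a V - b V ln V at the requested times."""
    t = _validate_times(times)
    if v0 <= 0:
        raise InputError(f"Gompertz requires initial volume > 0 (ln V), got {v0}")
    if t.size == 1:
        return GrowthCurve(t, np.array([v0]))

    def rhs(_t, y):
        return params.a * y - params.b * y * np.log(y)

    v = _integrate_scalar(rhs, v0, t)
    return GrowthCurve(t, np.clip(v, 0.0, None))


@dataclass
class FitResult:
    """Outcome of a growth-curve fit.

    ``converged`` reflects optimizer status; ``identifiable`` is False when
    the Jacobian at the solution is numerically rank-deficient (e.g. fitting
    a logistic to data already sitting at carrying capacity, where `a`
    carries no information).  Flagged results are returned, not raised.
    """

    model: str
    params: LogisticParams | GompertzParams
    rss: float
    converged: bool
    identifiable: bool
    message: str = ""
    n_points: int = 0
    v0: float = float("nan")

    @property
    def flagged(self) -> bool:
        return not (self.converged and self.identifiable)


def _logistic_guess(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    K0 = max(float(v.max()) * 1.05, 1e-6)
    # early-phase exponential slope as the rate guess
    with np.errstate(divide="ignore"):
        logv = np.log(np.clip(v, 1e-12, None))
    span = t[-1] - t[0]
    a0 = (logv[min(3, len(v) - 1)] - logv[0]) / max(t[min(3, len(t) - 1)] - t[0], 1e-9)
    if not np.isfinite(a0) or a0 <= 0:
        a0 = 1.0 / max(span, 1.0)
    return float(a0), K0


def _gompertz_guess(t: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    plateau = max(float(v.max()) * 1.05, 1.5)
    b0 = 0.1
    return b0 * np.log(plateau), b0


def fit_growth_curve(
    data: GrowthCurve,
    model: str = "logistic",
    initial_guess: LogisticParams | GompertzParams | None = None,
    log_space: bool = False,
) -> FitResult:
    """Fit logistic or Gompertz parameters to a time-volume curve.

    Ordinary least squares on volumes by default; ``log_space=True`` fits on
    log-volumes instead (appropriate for multiplicative noise).  Requires at
    least 3 points and strictly positive volumes.  Non-convergence and
    unidentifiable parameters are flagged on the result, not raised.
    """
    if model not in ("logistic", "gompertz"):
        raise InputError(f"unknown model {model!r}; expected 'logistic' or 'gompertz'")
    t, v = data.times, data.volumes
    if len(data) < 3:
        raise InputError(f"need at least 3 data points to fit, got {len(data)}")
    if np.any(v <= 0):
        raise InputError("fitting requires strictly positive volumes")

    # The starting volume is a nuisance parameter: fixing it to the (noisy)
    # first observation would bias the model parameters.
    if model == "logistic":
        closed = lambda x: logistic_solution(LogisticParams(x[0], x[1]), x[2], t)
        if initial_guess is not None:
            x0 = [initial_guess.a, initial_guess.K, float(v[0])]
        else:
            x0 = [*_logistic_guess(t, v), float(v[0])]
    else:
        closed = lambda x: gompertz_solution(GompertzParams(x[0], x[1]), x[2], t)
        if initial_guess is not None:
            x0 = [initial_guess.a, initial_guess.b, float(v[0])]
        else:
            x0 = [*_gompertz_guess(t, v), float(v[0])]

    def residuals(x):
        try:
            pred = closed(x)
        except InputError:
            return np.full_like(v, 1e12)
        if log_space:
            return np.log(np.clip(pred, 1e-300, None)) - np.log(v)
        return pred - v

    res = least_squares(
        residuals,
        x0,
        bounds=([1e-12, 1e-12, 1e-12], [np.inf, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    rss = float(np.sum((closed(res.x) - v) ** 2))

    # rank-deficient Jacobian at the optimum => some parameter unidentifiable
    sv = np.linalg.svd(res.jac, compute_uv=False)
    identifiable = bool(sv[0] > 0 and sv[-1] / sv[0] > 1e-8)

    if model == "logistic":
        fitted: LogisticParams | GompertzParams = LogisticParams(res.x[0], res.x[1])
    else:
        fitted = GompertzParams(res.x[0], res.x[1])
    return FitResult(
        model=model,
        params=fitted,
        rss=rss,
        converged=bool(res.success),
        identifiable=identifiable,
        message=str(res.message),
        n_points=len(data),
        v0=float(res.x[2]),
    )


def save_growth_params(params_by_model: dict, path) -> None:
    """Write parameter sets keyed by model name ("logistic"/"gompertz") to
    YAML, or JSON when the path ends in .json."""
    blocks = {}
    for name, p in params_by_model.items():
        if isinstance(p, LogisticParams):
            blocks[name] = {"a": p.a, "K": p.K}
        elif isinstance(p, GompertzParams):
            blocks[name] = {"a": p.a, "b": p.b}
        else:
            raise InputError(f"unknown parameter object for model {name!r}")
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(blocks, indent=2))
    else:
        path.write_text(yaml.safe_dump(blocks, sort_keys=False))


def load_growth_params(path) -> dict:
    """Read parameter sets keyed by model name; inverse of save_growth_params."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InputError("growth-parameter file must map model names to blocks")
    out: dict = {}
    for name, block in data.items():
        if name == "logistic":
            out[name] = LogisticParams(**block)
        elif name == "gompertz":
            out[name] = GompertzParams(**block)
        else:
            raise InputError(f"unknown growth model {name!r} in parameter file")
    return out
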
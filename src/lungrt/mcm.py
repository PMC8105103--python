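"""Multicomponent tumor-growth model (MCM).

The tumor colony is split into M active sub-populations T_1..T_M, each
growing logistically with its own rate a_m and carrying capacity K_m, a
quiescent pool Q (cells that have suspended division but can re-enter the
active pool), and a non-dividing pool ND (dead/dying cells cleared into the
blood at rate eta).  Volumes exchange between compartments at first-order
rates (per day):

    dV_m/dt  = a_m V_m (1 - V_m/K_m) + p_Qm V_Q - (p_mQ + p_mND) V_m
    dV_Q/dt  = sum_m p_mQ V_m - (sum_m p_Qm + p_QND) V_Q
    dV_ND/dt = sum_m p_mND V_m + p_QND V_Q - eta V_ND

Note on the transfer coefficients: the p_ij are used here as first-order
rate constants with units of 1/day (they multiply volumes inside an ODE),
even though the compartment diagram labels them as transition
"probabilities".  The default values carry Day^-1 units, which only makes
sense under the rate reading; this interpretation is deliberate and applies
everywhere in the package.

With M = 1 and all coupling rates zero the system reduces exactly to the
logistic law in :mod:`lungrt.growth`.  The default configuration uses M = 2
(a radioresistant, faster-growing T_1 and a radiosensitive T_2), matching
the published NSCLC parameter set exposed as ``CompartmentParams.default()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InputError, SimulationError
from .growth import RTOL, ATOL, _ODE_METHOD, _validate_times

__all__ = [
    "CompartmentParams",
    "TumorState",
    "Trajectory",
    "FractionEvent",
    "mcm_rhs",
    "simulate_mcm",
    "total_volume",
]

# negative excursions beyond this magnitude indicate real instability,
# not solver round-off, and raise instead of being clamped
NEG_CLAMP_LIMIT = -1e-6


def _rates(x, n: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.shape != (n,):
        raise InputError(f"{name} must have length {n}, got shape {arr.shape}")
    if np.any(arr < 0):
        raise InputError(f"{name} entries must be >= 0")
    return arr


@dataclass(frozen=True)
class CompartmentParams:
    """Rates of the M-active / quiescent / non-dividing system.

    Arrays are indexed by active compartment m = 0..M-1.  All rates are per
    day, capacities in mm^3.

    a : logistic growth rate of each active type
    K : carrying capacity of each active type
    p_Qm : transfer rate quiescent -> active m
    p_mQ : transfer rate active m -> quiescent
    p_mND : transfer rate active m -> non-dividing
    p_QND : transfer rate quiescent -> non-dividing
    eta : clearance rate of non-dividing volume into the blood
    """

    a: np.ndarray
    K: np.ndarray
    p_Qm: np.ndarray
    p_mQ: np.ndarray
    p_mND: np.ndarray
    p_QND: float
    eta: float

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        M = a.size
        if M < 1:
            raise InputError("need at least one active compartment")
        if np.any(a < 0):
            raise InputError("growth rates a must be >= 0")
        K = _rates(self.K, M, "K")
        if np.any(K <= 0):
            raise InputError("carrying capacities K must be > 0")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "p_Qm", _rates(self.p_Qm, M, "p_Qm"))
        object.__setattr__(self, "p_mQ", _rates(self.p_mQ, M, "p_mQ"))
        object.__setattr__(self, "p_mND", _rates(self.p_mND, M, "p_mND"))
        if self.p_QND < 0 or self.eta < 0:
            raise InputError("p_QND and eta must be >= 0")
        object.__setattr__(self, "p_QND", float(self.p_QND))
        object.__setattr__(self, "eta", float(self.eta))

    @property
    def M(self) -> int:
        """Number of active compartments."""
        return int(self.a.size)

    @classmethod
    def default(cls) -> "CompartmentParams":
        """Published NSCLC two-compartment parameter set."""
        return cls(
            a=[0.862, 0.501],
            K=[1397.0, 1174.0],
            p_Qm=[0.1, 0.1],
            p_mQ=[0.2, 0.2],
            p_mND=[0.2, 0.2],
            p_QND=0.09,
            eta=0.4,
        )

    def to_dict(self) -> dict:
        return {
            "a": self.a.tolist(),
            "K": self.K.tolist(),
            "p_Qm": self.p_Qm.tolist(),
            "p_mQ": self.p_mQ.tolist(),
            "p_mND": self.p_mND.tolist(),
            "p_QND": self.p_QND,
            "eta": self.eta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentParams":
        return cls(**d)


@dataclass
class TumorState:
    """Compartment volumes (mm^3): active V[m], quiescent V_Q, non-dividing V_ND."""

    V: np.ndarray
    V_Q: float = 0.0
    V_ND: float = 0.0

    def __post_init__(self) -> None:
        self.V = np.atleast_1d(np.asarray(self.V, dtype=float))
        self.V_Q = float(self.V_Q)
        self.V_ND = float(self.V_ND)
        if np.any(self.V < 0) or self.V_Q < 0 or self.V_ND < 0:
            raise InputError("compartment volumes must be >= 0")

    @property
    def M(self) -> int:
        return int(self.V.size)

    def to_vector(self) -> np.ndarray:
        """Pack as [V_1..V_M, V_Q, V_ND]."""
        return np.concatenate([self.V, [self.V_Q, self.V_ND]])

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "TumorState":
        y = np.asarray(y, dtype=float)
        return cls(V=y[:-2].copy(), V_Q=float(y[-2]), V_ND=float(y[-1]))

    def labels(self) -> list[str]:
        return [f"T{m + 1}" for m in range(self.M)] + ["Q", "ND"]

    def to_dict(self) -> dict:
        return {"V": self.V.tolist(), "V_Q": self.V_Q, "V_ND": self.V_ND}

    @classmethod
    def from_dict(cls, d: dict) -> "TumorState":
        return cls(**d)

    @classmethod
    def default_init(cls, M: int = 2) -> "TumorState":
        """Seed state for bare growth runs: 1 mm^3 per active type, empty Q/ND."""
        return cls(V=np.ones(M), V_Q=0.0, V_ND=0.0)


def total_volume(state: TumorState, which: str = "all") -> float:
    """Summed volume of the requested compartments.

    ``which``: "all" (active + Q + ND), "active" (sum of V_m), or a
    per-compartment label like "T1", "Q", "ND".
    """
    if which == "all":
        return float(state.V.sum() + state.V_Q + state.V_ND)
    if which == "active":
        return float(state.V.sum())
    if which == "Q":
        return state.V_Q
    if which == "ND":
        return state.V_ND
    if which.startswith("T"):
        try:
            m = int(which[1:]) - 1
        except ValueError:
            raise InputError(f"unknown volume selector {which!r}")
        if 0 <= m < state.M:
            return float(state.V[m])
    raise InputError(f"unknown volume selector {which!r}")


def _rhs_vec(y: np.ndarray, p: CompartmentParams) -> np.ndarray:
    V = y[: p.M]
    VQ = y[p.M]
    VND = y[p.M + 1]
    dV = p.a * V * (1.0 - V / p.K) + p.p_Qm * VQ - (p.p_mQ + p.p_mND) * V
    dVQ = float(p.p_mQ @ V) - (p.p_Qm.sum() + p.p_QND) * VQ
    dVND = float(p.p_mND @ V) + p.p_QND * VQ - p.eta * VND
    return np.concatenate([dV, [dVQ, dVND]])


def mcm_rhs(state: TumorState, params: CompartmentParams) -> TumorState:
    """Time-derivatives (mm^3/day) of every compartment at ``state``.

    Returned packed in a TumorState-shaped container (values may be negative).
    """
    if state.M != params.M:
        raise InputError(f"state has M={state.M} but params have M={params.M}")
    d = _rhs_vec(state.to_vector(), params)
    out = TumorState.__new__(TumorState)  # bypass non-negativity validation
    out.V = d[: params.M]
    out.V_Q = float(d[params.M])
    out.V_ND = float(d[params.M + 1])
    return out


@dataclass
class FractionEvent:
    """Record of one applied radiation fraction."""

    index: int
    time: float
    dose: float


@dataclass
class Trajectory:
    """Sampled compartment volumes over time plus the fraction log.

    ``states`` has shape (n_times, M + 2) with columns T1..TM, Q, ND.
    """

    times: np.ndarray
    states: np.ndarray
    event_log: list[FractionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = _validate_times(self.times)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.shape[0] != self.times.size:
            raise InputError("times and states length mismatch")

    @property
    def M(self) -> int:
        return int(self.states.shape[1] - 2)

    def state_at(self, i: int) -> TumorState:
        return TumorState.from_vector(self.states[i])

    @property
    def final_state(self) -> TumorState:
        return self.state_at(-1)

    def labels(self) -> list[str]:
        return [f"T{m + 1}" for m in range(self.M)] + ["Q", "ND"]

    def total(self, which: str = "all") -> np.ndarray:
        """Per-time summed volume ("all" or "active")."""
        if which == "all":
            return self.states.sum(axis=1)
        if which == "active":
            return self.states[:, : self.M].sum(axis=1)
        raise InputError(f"unknown selector {which!r}")

    def to_wide_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.labels())
        df.insert(0, "time_days", self.times)
        df["total"] = self.states.sum(axis=1)
        return df

    def to_long_frame(self) -> pd.DataFrame:
        wide = self.to_wide_frame().drop(columns="total")
        return wide.melt(
            id_vars="time_days", var_name="compartment", value_name="volume_mm3"
        )

    def write_csv(self, path, layout: str = "wide") -> None:
        if layout == "wide":
            self.to_wide_frame().to_csv(path, index=False)
        elif layout == "long":
            self.to_long_frame().to_csv(path, index=False)
        else:
            raise InputError(f"unknown trajectory layout {layout!r}")

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.index, e.time, e.dose) for e in self.event_log],
            columns=["fraction", "time_days", "dose_gy"],
        )


def _clamp(y: np.ndarray, when: str) -> np.ndarray:
    low = y.min() if y.size else 0.0
    if low < NEG_CLAMP_LIMIT:
        raise SimulationError(
            f"compartment volume fell to {low:.3e} mm^3 ({when}); "
            "the trajectory is numerically unstable"
        )
    return np.clip(y, 0.0, None)


def _integrate_segment(
    params: CompartmentParams,
    y0: np.ndarray,
    times: np.ndarray,
    rhs=None,
) -> np.ndarray:
    """Integrate the system over ``times`` and return states row-wise."""
    if times.size == 1:
        return y0[None, :].copy()
    sol = solve_ivp(
        (lambda t, y: _rhs_vec(y, params)) if rhs is None else rhs,
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method=_ODE_METHOD,
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else None
        raise SimulationError(f"MCM solver failed: {sol.message}", last_time=last)
    out = sol.y.T
    return np.vstack([_clamp(row, f"t={t:g}") for row, t in zip(out, times)])


def simulate_mcm(
    params: CompartmentParams, init: TumorState, times
) -> Trajectory:
    """Integrate the multicomponent system from ``init`` at the requested times."""
    t = _validate_times(times)
    if init.M != params.M:
        raise InputError(f"init has M={init.M} but params have M={params.M}")
    states = _integrate_segment(params, init.to_vector(), t)
    return Trajectory(times=t, states=states)
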
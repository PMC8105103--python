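"""Linear-quadratic radiation kill and fractionated-course simulation.

A radiation dose D (Gy) leaves a surviving fraction

    S = exp(-alpha D - beta D^2)

of the cells it hits (the linear-quadratic model; alpha/beta is the dose at
which the linear and quadratic contributions are equal, ~10-20 Gy for lung
tumors).  Radiation stops proliferation by breaking double-stranded DNA, so
it hits the active compartments and the quiescent pool, each with its own
(alpha, beta), but never the non-dividing pool.

A fraction can be applied two ways:

* **impulse** (default): delivery takes minutes against day-scale growth,
  so each fraction instantaneously multiplies V_m and V_Q by their LQ
  survivals.  This keeps the per-fraction survival exactly equal to the LQ
  formula regardless of delivery time.
* **window**: the kill is spread over the fraction's duration t_R as an
  extra ODE term -(alpha r + 2 beta r^2) V with constant dose rate
  r = D / t_R, integrated jointly with growth and transitions.  With growth
  off, the window survival is exp(-(alpha D + 2 beta D^2 / t_R)), which
  coincides with the LQ survival exactly at t_R = 2 time units; the impulse
  form is treated as ground truth and the window form is provided for
  studying delivery-time effects.

A course is a sequence of timed fractions (``FractionationPlan``); between
fractions the untreated multicomponent system grows freely.  The course
simulator returns both a sampled trajectory and a ``TreatmentResult``
carrying pre/post volumes and treatment ratios (post/pre, lower is better)
per compartment and overall.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .mcm import (
    CompartmentParams,
    FractionEvent,
    Trajectory,
    TumorState,
    _integrate_segment,
    _rhs_vec,
)

__all__ = [
    "RadiosensitivityParams",
    "Fraction",
    "FractionationPlan",
    "TreatmentResult",
    "lq_survival",
    "apply_fraction_impulse",
    "integrate_fraction_window",
    "simulate_course",
]


@dataclass(frozen=True)
class RadiosensitivityParams:
    """Per-compartment LQ coefficients.

    alpha (Gy^-1) and beta (Gy^-2) are arrays over the active types;
    alpha_Q/beta_Q apply to the quiescent pool.  The non-dividing pool has
    no kill term.  All coefficients are non-negative.
    """

    alpha: np.ndarray
    beta: np.ndarray
    alpha_Q: float
    beta_Q: float

    def __post_init__(self) -> None:
        alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if alpha.shape != beta.shape:
            raise InputError("alpha and beta must have the same length")
        if np.any(alpha < 0) or np.any(beta < 0) or self.alpha_Q < 0 or self.beta_Q < 0:
            raise InputError("LQ coefficients must be >= 0")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "alpha_Q", float(self.alpha_Q))
        object.__setattr__(self, "beta_Q", float(self.beta_Q))

    @property
    def M(self) -> int:
        return int(self.alpha.size)

    @classmethod
    def default(cls) -> "RadiosensitivityParams":
        """Published NSCLC two-compartment LQ set (T1 radioresistant, T2 sensitive)."""
        return cls(
            alpha=[0.194, 0.3705],
            beta=[0.063, 0.02335],
            alpha_Q=0.3,
            beta_Q=0.15,
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "alpha_Q": self.alpha_Q,
            "beta_Q": self.beta_Q,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadiosensitivityParams":
        return cls(**d)


def lq_survival(dose: float, alpha, beta):
    """LQ surviving fraction exp(-alpha*dose - beta*dose^2); dose in Gy."""
    if np.any(np.asarray(dose) < 0):
        raise InputError(f"dose must be >= 0, got {dose}")
    return np.exp(-(np.asarray(alpha) * dose + np.asarray(beta) * dose**2))


@dataclass(frozen=True)
class Fraction:
    """One radiation delivery: start time (days from course start), dose (Gy),
    and duration (days; 0 means the fraction is an instantaneous impulse)."""

    start_time: float
    dose: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise InputError(f"fraction dose must be > 0, got {self.dose}")
        if self.duration < 0:
            raise InputError(f"fraction duration must be >= 0, got {self.duration}")

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass
class FractionationPlan:
    """An ordered, non-overlapping sequence of fractions."""

    fractions: list[Fraction]
    label: str = ""

    def __post_init__(self) -> None:
        fr = list(self.fractions)
        for prev, nxt in zip(fr, fr[1:]):
            if not nxt.start_time > prev.start_time:
                raise InputError("fraction start times must be strictly increasing")
            if prev.end_time > nxt.start_time:
                raise InputError(
                    f"fractions overlap: one ends at t={prev.end_time:g} after "
                    f"the next starts at t={nxt.start_time:g}"
                )
        self.fractions = fr

    def __len__(self) -> int:
        return len(self.fractions)

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)

    @property
    def total_dose(self) -> float:
        return float(sum(f.dose for f in self.fractions))

    @property
    def course_length(self) -> float:
        """Days from the first fraction's start to the last fraction's end."""
        if not self.fractions:
            return 0.0
        return self.fractions[-1].end_time - self.fractions[0].start_time

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "fractions": [
                {"start_time": f.start_time, "dose": f.dose, "duration": f.duration}
                for f in self.fractions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FractionationPlan":
        return cls(
            fractions=[Fraction(**f) for f in d["fractions"]],
            label=d.get("label", ""),
        )


def apply_fraction_impulse(
    state: TumorState, dose: float, rs: RadiosensitivityParams
) -> TumorState:
    """Instantaneous LQ hit: scale V_m and V_Q by their survivals, leave V_ND."""
    if state.M != rs.M:
        raise InputError(f"state has M={state.M} but radiosensitivity has M={rs.M}")
    if dose < 0:
        raise InputError(f"dose must be >= 0, got {dose}")
    return TumorState(
        V=state.V * lq_survival(dose, rs.alpha, rs.beta),
        V_Q=state.V_Q * float(lq_survival(dose, rs.alpha_Q, rs.beta_Q)),
        V_ND=state.V_ND,
    )


def _irradiated_rhs(params: CompartmentParams, rs: RadiosensitivityParams, rate: float):
    """RHS of the growth system plus constant-dose-rate kill terms."""
    kill_m = rs.alpha * rate + 2.0 * rs.beta * rate**2
    kill_q = rs.alpha_Q * rate + 2.0 * rs.beta_Q * rate**2

    def rhs(_t, y):
        d = _rhs_vec(y, params)
        d[: params.M] -= kill_m * y[: params.M]
        d[params.M] -= kill_q * y[params.M]
        return d

    return rhs


def integrate_fraction_window(
    state: TumorState,
    dose: float,
    duration: float,
    params: CompartmentParams,
    rs: RadiosensitivityParams,
) -> TumorState:
    """Deliver ``dose`` at constant rate dose/duration while the tumor grows.

    Integrates growth, transitions and kill jointly over the window.  Use
    :func:`apply_fraction_impulse` for instantaneous delivery (duration 0).
    """
    if state.M != params.M or state.M != rs.M:
        raise InputError("state, params and radiosensitivity disagree on M")
    if not duration > 0:
        raise InputError(
            "window integration needs duration > 0; use the impulse form otherwise"
        )
    if dose < 0:
        raise InputError(f"dose must be >= 0, got {dose}")
    rate = dose / duration
    times = np.array([0.0, duration])
    rhs = _irradiated_rhs(params, rs, rate)
    states = _integrate_segment(params, state.to_vector(), times, rhs=rhs)
    return TumorState.from_vector(states[-1])


_RATIO_KEYS = ("total", "active")


@dataclass
class TreatmentResult:
    """Pre/post volumes and treatment ratios of one simulated course.

    ``pre`` is the state at the first fraction's start; ``post`` the state
    at the evaluation time (end of the last fraction plus any follow-up).
    Keys are compartment labels (T1..TM, Q, ND) plus "active" and "total".
    ``ratio[k] = post[k] / pre[k]``; NaN where the pre-volume is zero.
    """

    pre: dict[str, float]
    post: dict[str, float]
    ratio: dict[str, float]
    total_dose: float
    n_fractions: int
    course_days: float
    label: str = ""
    mode: str = "impulse"
    followup_days: float = 0.0
    eval_day: float | None = None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mode": self.mode,
            "total_dose_gy": self.total_dose,
            "n_fractions": self.n_fractions,
            "course_days": self.course_days,
            "followup_days": self.followup_days,
            "eval_day": self.eval_day,
            "pre_volume_mm3": self.pre,
            "post_volume_mm3": self.post,
            "treatment_ratio": self.ratio,
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _volume_dict(state: TumorState) -> dict[str, float]:
    d = {f"T{m + 1}": float(v) for m, v in enumerate(state.V)}
    d["Q"] = state.V_Q
    d["ND"] = state.V_ND
    d["active"] = float(state.V.sum())
    d["total"] = float(state.V.sum() + state.V_Q + state.V_ND)
    return d


def _ratio_dict(pre: dict[str, float], post: dict[str, float]) -> dict[str, float]:
    return {
        k: (post[k] / pre[k]) if pre[k] > 0 else float("nan") for k in pre
    }


def _segment_times(t0: float, t1: float, samples_per_day: float) -> np.ndarray:
    """Sample grid over [t0, t1] including both endpoints."""
    if t1 <= t0:
        return np.array([t0])
    n = max(int(np.ceil((t1 - t0) * samples_per_day)), 1)
    return np.linspace(t0, t1, n + 1)


def simulate_course(
    params: CompartmentParams,
    rs: RadiosensitivityParams,
    plan: FractionationPlan,
    init: TumorState,
    mode: str = "impulse",
    run_in_days: float = 0.0,
    followup_days: float = 0.0,
    samples_per_day: float = 8.0,
    eval_day: float | None = None,
) -> tuple[Trajectory, TreatmentResult]:
    """Simulate a fractionated radiotherapy course.

    The tumor grows untreated from ``init`` for ``run_in_days``, then the
    plan's fractions are applied at their scheduled times (measured from the
    end of the run-in).  Between fractions the untreated system evolves
    freely.  By default the treatment ratio compares the state at the first
    fraction's start with the state ``followup_days`` after the last
    fraction ends.

    mode : "impulse" applies each fraction as an instantaneous LQ hit;
        "window" integrates each fraction's kill over its stated duration
        (every fraction must then have duration > 0).
    eval_day : optional common calendar horizon.  When set, the post state
        for the treatment ratio is read at ``eval_day`` days after the
        course start instead of at the course end — the way one reads
        competing plans off a shared time axis.  The state is taken just
        before any fraction delivered at that exact instant (left limit),
        and integration is extended past the course end if needed.
    """
    if mode not in ("impulse", "window"):
        raise InputError(f"unknown fraction mode {mode!r}")
    if run_in_days < 0 or followup_days < 0:
        raise InputError("run_in_days and followup_days must be >= 0")
    if params.M != rs.M or init.M != params.M:
        raise InputError("params, radiosensitivity and init disagree on M")
    if plan.fractions and plan.fractions[0].start_time < 0:
        raise InputError("fractions cannot be scheduled before the course start")
    if mode == "window" and any(f.duration <= 0 for f in plan.fractions):
        raise InputError("window mode requires every fraction to have duration > 0")
    if eval_day is not None and eval_day < 0:
        raise InputError("eval_day must be >= 0 (days after course start)")
    eval_T = None if eval_day is None else run_in_days + eval_day

    def grid(t0: float, t1: float, spd: float) -> np.ndarray:
        g = _segment_times(t0, t1, spd)
        if eval_T is not None and t0 < eval_T < t1:
            g = np.union1d(g, [eval_T])
        return g

    seg_times: list[np.ndarray] = []
    seg_states: list[np.ndarray] = []
    events: list[FractionEvent] = []

    def extend(times: np.ndarray, states: np.ndarray) -> None:
        if seg_times and times.size and np.isclose(times[0], seg_times[-1][-1]):
            # keep the duplicated boundary point: it shows the impulse jump
            pass
        seg_times.append(times)
        seg_states.append(states)

    y = init.to_vector()
    t = 0.0

    if run_in_days > 0:
        times = grid(0.0, run_in_days, samples_per_day)
        states = _integrate_segment(params, y, times)
        extend(times, states)
        y = states[-1]
        t = run_in_days

    course_start = t
    pre_state = TumorState.from_vector(y)

    for i, fr in enumerate(plan.fractions):
        f_start = course_start + fr.start_time
        if f_start < t - 1e-12:
            raise InputError(
                f"fraction {i + 1} at t={fr.start_time:g} overlaps the previous one"
            )
        if f_start > t:
            times = grid(t, f_start, samples_per_day)
            states = _integrate_segment(params, y, times)
            extend(times, states)
            y = states[-1]
            t = f_start
        if i == 0:
            pre_state = TumorState.from_vector(y)
        if mode == "impulse":
            hit = apply_fraction_impulse(TumorState.from_vector(y), fr.dose, rs)
            y = hit.to_vector()
            extend(np.array([t]), y[None, :])
        else:
            rate = fr.dose / fr.duration
            times = grid(t, t + fr.duration, max(samples_per_day, 4 / fr.duration))
            rhs = _irradiated_rhs(params, rs, rate)
            states = _integrate_segment(params, y, times, rhs=rhs)
            extend(times, states)
            y = states[-1]
            t = t + fr.duration
        events.append(FractionEvent(index=i + 1, time=f_start, dose=fr.dose))

    horizon = t + followup_days if plan.fractions else course_start + followup_days
    if eval_T is not None:
        horizon = max(horizon, eval_T)
    if horizon > t:
        times = grid(t, horizon, samples_per_day)
        states = _integrate_segment(params, y, times)
        extend(times, states)
        y = states[-1]
        t = horizon

    if not seg_times:  # degenerate: nothing to integrate at all
        extend(np.array([t]), y[None, :])

    if eval_T is None:
        post_state = TumorState.from_vector(y)
    else:
        # left limit at the evaluation instant: first recorded sample there
        post_state = None
        for times, states in zip(seg_times, seg_states):
            hits = np.flatnonzero(np.abs(times - eval_T) <= 1e-9)
            if hits.size:
                post_state = TumorState.from_vector(states[hits[0]])
                break
        if post_state is None:
            raise InputError(
                f"eval_day={eval_day:g} lies outside the simulated horizon"
            )

    # assemble the sampled trajectory, dropping duplicate boundary times
    # except across impulse jumps (tiny forward nudge keeps times increasing)
    all_t: list[float] = []
    all_s: list[np.ndarray] = []
    eps = 1e-9
    for times, states in zip(seg_times, seg_states):
        for tt, ss in zip(times, states):
            if all_t and tt <= all_t[-1]:
                if np.allclose(ss, all_s[-1]):
                    continue
                tt = all_t[-1] + eps
            all_t.append(float(tt))
            all_s.append(ss)
    traj = Trajectory(
        times=np.array(all_t), states=np.vstack(all_s), event_log=events
    )

    pre = _volume_dict(pre_state)
    post = _volume_dict(post_state)
    result = TreatmentResult(
        pre=pre,
        post=post,
        ratio=_ratio_dict(pre, post),
        total_dose=plan.total_dose,
        n_fractions=plan.n_fractions,
        course_days=plan.course_length,
        label=plan.label,
        mode=mode,
        followup_days=followup_days,
        eval_day=eval_day,
    )
    return traj, result
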
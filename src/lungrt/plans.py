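"""Fractionation-plan builders, the treatment-ratio metric and plan comparison.

A ``PlanSpec`` describes a clinical schedule the way a prescription does —
total dose, number of fractions, fractions per day, treatment days per week
— and ``build_plan`` expands it into explicitly timed fractions.  Day 0 is
a Monday-equivalent; weekends (day index mod 7 >= treatment_days_per_week)
are skipped deterministically, and multiple daily fractions are separated
by a fixed intra-day gap (default 6 h).

``PRESETS`` ships representative schedules for the three clinical scenarios
studied with this model:

* SBRT — stereotactic body radiotherapy, few large fractions
  (48 Gy/4 Fr, 60 Gy/8 Fr, 50 Gy/5 Fr and a single 23.5 Gy fraction);
* CFRT — conventional fractionation (60 Gy/30 Fr and a 70 Gy/35 Fr variant
  at 2 Gy/fraction, plus a 2.5 Gy/fraction variant at the same 60 Gy);
* HFRT — the accelerated schedule delivering 60 Gy/30 Fr at 2 fractions
  per day.

``compare_plans`` runs each plan from the identical pre-treatment state and
tabulates per-compartment treatment ratios.  The table ranks tumor control
only; normal-tissue toxicity is outside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .mcm import CompartmentParams, TumorState
from .radio import (
    Fraction,
    FractionationPlan,
    RadiosensitivityParams,
    TreatmentResult,
    simulate_course,
)

__all__ = [
    "PlanSpec",
    "ComparisonReport",
    "PRESETS",
    "PRESET_GROUPS",
    "build_plan",
    "get_preset",
    "treatment_ratio",
    "compare_plans",
]


@dataclass(frozen=True)
class PlanSpec:
    """Prescription-style description of a fractionation schedule."""

    total_dose: float
    n_fractions: int
    fractions_per_day: int = 1
    treatment_days_per_week: int = 5
    intra_day_gap_hours: float = 6.0
    fraction_duration: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if not self.total_dose > 0:
            raise InputError(f"total dose must be > 0, got {self.total_dose}")
        if self.n_fractions < 1:
            raise InputError(f"need at least 1 fraction, got {self.n_fractions}")
        if self.fractions_per_day < 1:
            raise InputError("fractions_per_day must be >= 1")
        if not 1 <= self.treatment_days_per_week <= 7:
            raise InputError("treatment_days_per_week must be in 1..7")
        if self.intra_day_gap_hours <= 0 and self.fractions_per_day > 1:
            raise InputError("intra_day_gap_hours must be > 0 for multiple daily fractions")
        gap_days = self.intra_day_gap_hours / 24.0
        if (self.fractions_per_day - 1) * gap_days + self.fraction_duration >= 1.0:
            raise InputError("daily fractions do not fit within one day")
        if self.fraction_duration < 0:
            raise InputError("fraction_duration must be >= 0")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions

    def to_dict(self) -> dict:
        return {
            "total_dose": self.total_dose,
            "n_fractions": self.n_fractions,
            "fractions_per_day": self.fractions_per_day,
            "treatment_days_per_week": self.treatment_days_per_week,
            "intra_day_gap_hours": self.intra_day_gap_hours,
            "fraction_duration": self.fraction_duration,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlanSpec":
        return cls(**d)


def build_plan(spec: PlanSpec) -> FractionationPlan:
    """Expand a PlanSpec into explicitly timed fractions.

    Fractions are placed on consecutive treatment days starting at day 0
    (a Monday), skipping non-treatment weekdays, ``fractions_per_day`` per
    treatment day separated by the intra-day gap, each of dose
    total_dose / n_fractions.
    """
    dose = spec.dose_per_fraction
    gap = spec.intra_day_gap_hours / 24.0
    fractions: list[Fraction] = []
    day = 0
    while len(fractions) < spec.n_fractions:
        if day % 7 < spec.treatment_days_per_week:
            for j in range(spec.fractions_per_day):
                if len(fractions) == spec.n_fractions:
                    break
                fractions.append(
                    Fraction(
                        start_time=day + j * gap,
                        dose=dose,
                        duration=spec.fraction_duration,
                    )
                )
        day += 1
    return FractionationPlan(fractions=fractions, label=spec.label or _auto_label(spec))


def _auto_label(spec: PlanSpec) -> str:
    base = f"{spec.total_dose:g} Gy/{spec.n_fractions} Fr"
    if spec.fractions_per_day > 1:
        base += f" ({spec.fractions_per_day}/day)"
    return base


def treatment_ratio(pre: float, post: float) -> float:
    """Tumor volume after treatment divided by the volume before; lower is better."""
    if not pre > 0:
        raise InputError(f"pre-treatment volume must be > 0, got {pre}")
    if post < 0:
        raise InputError(f"post-treatment volume must be >= 0, got {post}")
    return post / pre


# Representative schedules for the three clinical scenarios.
PRESETS: dict[str, PlanSpec] = {
    "sbrt-48-4": PlanSpec(48.0, 4, label="SBRT 48 Gy/4 Fr"),
    "sbrt-60-8": PlanSpec(60.0, 8, label="SBRT 60 Gy/8 Fr"),
    "sbrt-50-5": PlanSpec(50.0, 5, label="SBRT 50 Gy/5 Fr"),
    "sbrt-single": PlanSpec(23.5, 1, label="SBRT 23.5 Gy/1 Fr"),
    "cfrt-60-30": PlanSpec(60.0, 30, label="CFRT 60 Gy/30 Fr"),
    "cfrt-70-35": PlanSpec(70.0, 35, label="CFRT 70 Gy/35 Fr"),
    "cfrt-60-24": PlanSpec(60.0, 24, label="CFRT 60 Gy/24 Fr (2.5 Gy)"),
    "hfrt-60-30-bid": PlanSpec(
        60.0, 30, fractions_per_day=2, label="HFRT 60 Gy/30 Fr BID"
    ),
}

PRESET_GROUPS: dict[str, list[str]] = {
    "sbrt": ["sbrt-48-4", "sbrt-60-8", "sbrt-50-5", "sbrt-single"],
    "cfrt": ["cfrt-60-30", "cfrt-70-35", "cfrt-60-24"],
    "hfrt": ["cfrt-60-30", "hfrt-60-30-bid"],
}


def get_preset(name: str) -> PlanSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise InputError(
            f"unknown plan preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass
class ComparisonReport:
    """One row per plan: schedule summary plus treatment ratios."""

    frame: pd.DataFrame
    results: list[TreatmentResult | None] = field(default_factory=list)

    def write_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.frame)


def compare_plans(
    specs: list[PlanSpec],
    params: CompartmentParams | None = None,
    rs: RadiosensitivityParams | None = None,
    init: TumorState | None = None,
    mode: str = "impulse",
    run_in_days: float = 30.0,
    followup_days: float = 0.0,
    eval_day: float | None = None,
) -> ComparisonReport:
    """Simulate every plan from the identical pre-treatment state and tabulate.

    Per-plan simulation failures are captured as flagged rows (``error``
    column) rather than aborting the whole comparison.
    """
    params = params or CompartmentParams.default()
    rs = rs or RadiosensitivityParams.default()
    init = init or TumorState.default_init(params.M)

    rows = []
    results: list[TreatmentResult | None] = []
    ratio_keys = [f"T{m + 1}" for m in range(params.M)] + ["Q", "ND", "active", "total"]
    for spec in specs:
        row: dict = {
            "plan": spec.label or _auto_label(spec),
            "total_dose_gy": spec.total_dose,
            "dose_per_fraction_gy": spec.dose_per_fraction,
            "n_fractions": spec.n_fractions,
        }
        try:
            plan = build_plan(spec)
            _, result = simulate_course(
                params,
                rs,
                plan,
                init,
                mode=mode,
                run_in_days=run_in_days,
                followup_days=followup_days,
                eval_day=eval_day,
            )
            row["course_days"] = result.course_days
            for k in ratio_keys:
                row[f"ratio_{k}"] = result.ratio[k]
            row["error"] = ""
            results.append(result)
        except Exception as exc:  # flagged row, not a global failure
            row["course_days"] = np.nan
            for k in ratio_keys:
                row[f"ratio_{k}"] = np.nan
            row["error"] = str(exc)
            results.append(None)
        rows.append(row)
    return ComparisonReport(frame=pd.DataFrame(rows), results=results)
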
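"""Run configuration: strict YAML/JSON loading with validated defaults.

A ``RunConfig`` bundles everything a treatment simulation needs: the
compartment and radiosensitivity parameters, the initial state, the run-in
and follow-up windows, the fraction mode, and the plan (a preset name, an
inline prescription, or an explicit fraction list).  Omitted parameter
blocks fall back to the published NSCLC defaults.  Validation is strict and
fail-fast: unknown keys and invariant violations raise ``ConfigError``
naming the offending field — a silent default on a typo would corrupt a
plan comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError, InputError
from .mcm import CompartmentParams, TumorState
from .plans import PlanSpec, build_plan, get_preset
from .radio import FractionationPlan, RadiosensitivityParams

__all__ = ["RunConfig", "load_config", "save_config"]

_TOP_KEYS = {
    "compartments",
    "radiosensitivity",
    "init",
    "run_in_days",
    "followup_days",
    "mode",
    "plan",
    "samples_per_day",
    "eval_day",
}
_COMPARTMENT_KEYS = {"a", "K", "p_Qm", "p_mQ", "p_mND", "p_QND", "eta"}
_RS_KEYS = {"alpha", "beta", "alpha_Q", "beta_Q"}
_INIT_KEYS = {"V", "V_Q", "V_ND"}
_PLAN_KEYS = {
    "preset",
    "file",
    "fractions",
    "label",
    "total_dose",
    "n_fractions",
    "fractions_per_day",
    "treatment_days_per_week",
    "intra_day_gap_hours",
    "fraction_duration",
}


@dataclass
class RunConfig:
    """Fully validated configuration of one treatment simulation."""

    compartments: CompartmentParams
    radiosensitivity: RadiosensitivityParams
    init: TumorState
    run_in_days: float = 30.0
    followup_days: float = 0.0
    mode: str = "impulse"
    samples_per_day: float = 8.0
    eval_day: float | None = None
    plan_spec: PlanSpec | None = None
    plan: FractionationPlan | None = None

    def resolved_plan(self) -> FractionationPlan:
        if self.plan is not None:
            return self.plan
        if self.plan_spec is not None:
            return build_plan(self.plan_spec)
        raise ConfigError("configuration has no plan")

    def to_dict(self) -> dict:
        d: dict = {
            "compartments": self.compartments.to_dict(),
            "radiosensitivity": self.radiosensitivity.to_dict(),
            "init": self.init.to_dict(),
            "run_in_days": self.run_in_days,
            "followup_days": self.followup_days,
            "mode": self.mode,
            "samples_per_day": self.samples_per_day,
        }
        if self.eval_day is not None:
            d["eval_day"] = self.eval_day
        if self.plan_spec is not None:
            d["plan"] = self.plan_spec.to_dict()
        elif self.plan is not None:
            d["plan"] = self.plan.to_dict()
        return d


def _reject_unknown(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_plan(block: dict, base: Path | None) -> tuple[PlanSpec | None, FractionationPlan | None]:
    if not isinstance(block, dict):
        raise ConfigError("plan block must be a mapping")
    _reject_unknown(block, _PLAN_KEYS, "plan")
    sources = [k for k in ("preset", "file", "fractions", "total_dose") if k in block]
    if "preset" in block:
        if len(sources) > 1:
            raise ConfigError("plan: give exactly one of preset/file/fractions/prescription")
        try:
            return get_preset(block["preset"]), None
        except InputError as exc:
            raise ConfigError(str(exc)) from None
    if "file" in block:
        path = Path(block["file"])
        if base is not None and not path.is_absolute():
            path = base / path
        sub = _load_raw(path)
        return _parse_plan(sub if "fractions" in sub or "total_dose" in sub else sub.get("plan", sub), path.parent)
    if "fractions" in block:
        try:
            return None, FractionationPlan.from_dict(
                {"fractions": block["fractions"], "label": block.get("label", "")}
            )
        except (InputError, TypeError, KeyError) as exc:
            raise ConfigError(f"plan.fractions: {exc}") from None
    if "total_dose" in block:
        try:
            return PlanSpec.from_dict(block), None
        except (InputError, TypeError) as exc:
            raise ConfigError(f"plan: {exc}") from None
    raise ConfigError("plan block needs one of: preset, file, fractions, total_dose")


def _load_raw(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return data


def _config_from_dict(data: dict, base: Path | None = None) -> RunConfig:
    _reject_unknown(data, _TOP_KEYS, "config root")

    comp_block = data.get("compartments", {}) or {}
    _reject_unknown(comp_block, _COMPARTMENT_KEYS, "compartments")
    defaults = CompartmentParams.default().to_dict()
    try:
        compartments = CompartmentParams.from_dict({**defaults, **comp_block})
    except InputError as exc:
        raise ConfigError(f"compartments: {exc}") from None

    rs_block = data.get("radiosensitivity", {}) or {}
    _reject_unknown(rs_block, _RS_KEYS, "radiosensitivity")
    rs_defaults = RadiosensitivityParams.default().to_dict()
    try:
        rs = RadiosensitivityParams.from_dict({**rs_defaults, **rs_block})
    except InputError as exc:
        raise ConfigError(f"radiosensitivity: {exc}") from None

    init_block = data.get("init", None)
    if init_block is None:
        init = TumorState.default_init(compartments.M)
    else:
        _reject_unknown(init_block, _INIT_KEYS, "init")
        try:
            init = TumorState.from_dict(
                {"V": init_block.get("V", [1.0] * compartments.M),
                 "V_Q": init_block.get("V_Q", 0.0),
                 "V_ND": init_block.get("V_ND", 0.0)}
            )
        except InputError as exc:
            raise ConfigError(f"init: {exc}") from None

    mode = data.get("mode", "impulse")
    if mode not in ("impulse", "window"):
        raise ConfigError(f"mode must be 'impulse' or 'window', got {mode!r}")

    if "eval_day" in data and data["eval_day"] is not None:
        if not isinstance(data["eval_day"], (int, float)) or data["eval_day"] < 0:
            raise ConfigError("eval_day must be a non-negative number")
    for key in ("run_in_days", "followup_days", "samples_per_day"):
        if key in data and (not isinstance(data[key], (int, float)) or data[key] < 0):
            raise ConfigError(f"{key} must be a non-negative number")

    plan_spec, plan = (None, None)
    if "plan" in data:
        plan_spec, plan = _parse_plan(data["plan"], base)

    cfg = RunConfig(
        compartments=compartments,
        radiosensitivity=rs,
        init=init,
        run_in_days=float(data.get("run_in_days", 30.0)),
        followup_days=float(data.get("followup_days", 0.0)),
        mode=mode,
        samples_per_day=float(data.get("samples_per_day", 8.0)),
        eval_day=None if data.get("eval_day") is None else float(data["eval_day"]),
        plan_spec=plan_spec,
        plan=plan,
    )
    if init.M != compartments.M:
        raise ConfigError(
            f"init has {init.M} active compartments but model has {compartments.M}"
        )
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Missing parameter blocks get the published NSCLC defaults; unknown keys
    and invariant violations raise :class:`ConfigError` naming the field.
    """
    path = Path(path)
    return _config_from_dict(_load_raw(path), base=path.parent)


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML (or JSON by extension); round-trip stable."""
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
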
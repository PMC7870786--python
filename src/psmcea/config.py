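"""YAML/JSON serialization for scenario models and sensitivity specs."""

from __future__ import annotations

import hashlib
import json
from typing import Optional

import yaml

from .engine import (
    AdverseEvent,
    ModelSettings,
    NGSConfig,
    RatioCI,
    StrategyConfig,
    SubsequentRegimen,
)
from .exceptions import ConfigError
from .model import ScenarioModel
from .survival import SurvivalDistribution
from .uncertainty import ParamSpec


def strategy_to_dict(s: StrategyConfig) -> dict:
    d = {
        "name": s.name,
        "pfs_model": s.pfs_model.to_dict(),
        "os_model": s.os_model.to_dict(),
        "weekly_drug_cost": s.weekly_drug_cost,
        "price_discount": s.price_discount,
        "drug_cost_is_net": s.drug_cost_is_net,
        "p_subsequent_active": s.p_subsequent_active,
        "subsequent_mix": [
            {"label": r.label, "proportion": r.proportion, "monthly_cost": r.monthly_cost}
            for r in s.subsequent_mix
        ],
        "subsequent_duration_months": s.subsequent_duration_months,
        "supportive_care_cost_per_day": s.supportive_care_cost_per_day,
        "followup_cost_per_week": s.followup_cost_per_week,
        "terminal_cost": s.terminal_cost,
        "ae_events": [
            {
                "label": a.label,
                "probability": a.probability,
                "cost": a.cost,
                "disutility": a.disutility,
                "duration_weeks": a.duration_weeks,
            }
            for a in s.ae_events
        ],
    }
    if s.hr_pfs is not None:
        d["hr_pfs"] = {"value": s.hr_pfs.value, "low": s.hr_pfs.low, "high": s.hr_pfs.high}
    if s.hr_os is not None:
        d["hr_os"] = {"value": s.hr_os.value, "low": s.hr_os.low, "high": s.hr_os.high}
    if s.extrapolation_cutoffs is not None:
        d["extrapolation_cutoffs"] = list(s.extrapolation_cutoffs)
    if s.ngs is not None:
        d["ngs"] = {
            "test_cost": s.ngs.test_cost,
            "prevalence": s.ngs.prevalence,
            "mode": s.ngs.mode,
        }
    return d


def _ratio(d: Optional[dict]) -> Optional[RatioCI]:
    if d is None:
        return None
    return RatioCI(value=float(d["value"]), low=float(d["low"]), high=float(d["high"]))


def strategy_from_dict(d: dict) -> StrategyConfig:
    try:
        return StrategyConfig(
            name=d["name"],
            pfs_model=SurvivalDistribution.from_dict(d["pfs_model"]),
            os_model=SurvivalDistribution.from_dict(d["os_model"]),
            weekly_drug_cost=float(d["weekly_drug_cost"]),
            price_discount=float(d.get("price_discount", 0.15)),
            drug_cost_is_net=bool(d.get("drug_cost_is_net", True)),
            p_subsequent_active=float(d["p_subsequent_active"]),
            subsequent_mix=tuple(
                SubsequentRegimen(r["label"], float(r["proportion"]), float(r["monthly_cost"]))
                for r in d.get("subsequent_mix", [])
            ),
            subsequent_duration_months=float(d.get("subsequent_duration_months", 0.0)),
            supportive_care_cost_per_day=float(d["supportive_care_cost_per_day"]),
            followup_cost_per_week=float(d["followup_cost_per_week"]),
            terminal_cost=float(d["terminal_cost"]),
            hr_pfs=_ratio(d.get("hr_pfs")),
            hr_os=_ratio(d.get("hr_os")),
            extrapolation_cutoffs=(
                tuple(float(c) for c in d["extrapolation_cutoffs"])
                if d.get("extrapolation_cutoffs") else None
            ),
            ae_events=tuple(
                AdverseEvent(
                    a["label"], float(a["probability"]), float(a["cost"]),
                    float(a["disutility"]), float(a["duration_weeks"]),
                )
                for a in d.get("ae_events", [])
            ),
            ngs=(
                NGSConfig(
                    test_cost=float(d["ngs"]["test_cost"]),
                    prevalence=float(d["ngs"]["prevalence"]),
                    mode=d["ngs"].get("mode", "flat"),
                )
                if d.get("ngs") else None
            ),
        )
    except KeyError as exc:
        raise ConfigError(f"strategy config missing required field: {exc}") from exc


def model_to_dict(model: ScenarioModel, specs: Optional[list[ParamSpec]] = None) -> dict:
    st = model.settings
    d = {
        "label": model.label,
        "settings": {
            "horizon_weeks": st.horizon_weeks,
            "cycle_length_weeks": st.cycle_length_weeks,
            "annual_discount": st.annual_discount,
            "u_pfd": st.u_pfd,
            "u_pd": st.u_pd,
            "wtp": st.wtp,
            "half_cycle_correction": st.half_cycle_correction,
        },
        "reference": strategy_to_dict(model.reference),
        "intervention": strategy_to_dict(model.intervention),
    }
    if specs is not None:
        d["sensitivity"] = [s.to_dict() for s in specs]
    return d


def model_from_dict(d: dict) -> tuple[ScenarioModel, list[ParamSpec]]:
    try:
        st = d.get("settings", {})
        settings = ModelSettings(
            horizon_weeks=float(st.get("horizon_weeks", 520.0)),
            cycle_length_weeks=float(st.get("cycle_length_weeks", 1.0)),
            annual_discount=float(st.get("annual_discount", 0.03)),
            u_pfd=float(st.get("u_pfd", 0.76)),
            u_pd=float(st.get("u_pd", 0.37)),
            wtp=float(st.get("wtp", 150_000.0)),
            half_cycle_correction=bool(st.get("half_cycle_correction", False)),
        )
        model = ScenarioModel(
            reference=strategy_from_dict(d["reference"]),
            intervention=strategy_from_dict(d["intervention"]),
            settings=settings,
            label=d.get("label", ""),
        )
    except KeyError as exc:
        raise ConfigError(f"model config missing required field: {exc}") from exc
    specs = [ParamSpec.from_dict(s) for s in d.get("sensitivity", [])]
    return model, specs


def save_yaml(model: ScenarioModel, path, specs: Optional[list[ParamSpec]] = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model, specs), fh, sort_keys=False)


def load_yaml(path) -> tuple[ScenarioModel, list[ParamSpec]]:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError("config file must contain a mapping")
    return model_from_dict(d)


def config_hash(model: ScenarioModel, specs: Optional[list[ParamSpec]] = None) -> str:
    """Stable content hash of a model configuration."""
    blob = json.dumps(model_to_dict(model, specs), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()
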
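"""Synthetic inputs: simulated arm-level time-to-event data, emulated
curve-digitization output, and complete fixture model configurations.

Everything the downstream fitting / reconstruction / engine stages consume
can be generated here deterministically from a seed, so the whole pipeline is
testable without any external data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import benchmarks
from .engine import (
    AdverseEvent,
    ModelSettings,
    NGSConfig,
    RatioCI,
    StrategyConfig,
    SubsequentRegimen,
    WEEKS_PER_MONTH,
)
from .exceptions import ValidationError
from .model import ScenarioModel
from .reconstruct import DigitizedKM, PseudoIPD
from .survival import SurvivalDistribution, inverse_survival, survival_at
from .uncertainty import ParamSpec

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# arm-level event-time simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArmSpec:
    """One simulated arm: progression-time law plus an overall-survival rule.

    Overall survival is ``pfs + residual`` when ``residual_dist`` is given
    (progression precedes or coincides with death by construction); otherwise
    an independent draw from ``os_dist`` floored at the progression time.
    """

    name: str
    pfs_dist: SurvivalDistribution
    n: int
    followup: float  # administrative censoring time, native unit of pfs_dist
    residual_dist: Optional[SurvivalDistribution] = None
    os_dist: Optional[SurvivalDistribution] = None

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError("arm size must be >= 1")
        if self.followup < 0:
            raise ValidationError("follow-up must be >= 0")


@dataclass(frozen=True)
class SimScenario:
    """A reproducible simulation design: arms plus digitization layout."""

    arms: tuple[ArmSpec, ...]
    grid_step: float = 1.0       # digitization grid spacing, native time unit
    risk_interval: float = 6.0   # risk-table spacing, native time unit
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "arms", tuple(self.arms))
        if self.grid_step <= 0 or self.risk_interval <= 0:
            raise ValidationError("grid_step and risk_interval must be positive")


def _sample_times(dist: SurvivalDistribution, n: int, rng: np.random.Generator) -> np.ndarray:
    u = rng.uniform(size=n)
    return np.asarray(inverse_survival(dist, u), dtype=float)


def simulate_arm(arm: ArmSpec, rng: np.random.Generator) -> dict[str, PseudoIPD]:
    """Draw (PFS, OS) pairs with PFS <= OS, apply administrative censoring."""
    pfs = _sample_times(arm.pfs_dist, arm.n, rng)
    if arm.residual_dist is not None:
        os_t = pfs + _sample_times(arm.residual_dist, arm.n, rng)
    elif arm.os_dist is not None:
        os_t = np.maximum(pfs, _sample_times(arm.os_dist, arm.n, rng))
    else:
        os_t = pfs.copy()

    if arm.followup == 0:
        logger.warning("%s: follow-up is 0; every record is censored at 0", arm.name)

    def censor(times: np.ndarray) -> PseudoIPD:
        event = (times <= arm.followup).astype(int)
        obs = np.minimum(times, arm.followup)
        return PseudoIPD(records=tuple(zip(obs.tolist(), event.tolist())))

    out = {"pfs": censor(pfs), "os": censor(os_t)}
    if out["pfs"].n_events == 0 and out["os"].n_events == 0 and arm.followup > 0:
        logger.warning("%s: no events within follow-up (cure fraction too high?)", arm.name)
    return out


def simulate_ipd(scenario: SimScenario) -> dict[str, dict[str, PseudoIPD]]:
    """Per-arm, per-endpoint pseudo individual-patient datasets."""
    rng = np.random.default_rng(scenario.seed)
    return {arm.name: simulate_arm(arm, rng) for arm in scenario.arms}


# ---------------------------------------------------------------------------
# emulated digitization
# ---------------------------------------------------------------------------

def digitize_km(
    ipd: PseudoIPD,
    grid_step: float,
    risk_interval: float,
    jitter: float = 0.0,
    seed: int = 0,
) -> DigitizedKM:
    """Sample the exact KM estimator on a grid, with a matching risk table.

    ``jitter`` adds uniform digitization noise (+-jitter) to the sampled
    survival probabilities; the default 0 keeps round trips exact.
    """
    if len(ipd.records) == 0:
        raise ValidationError("cannot digitize an empty dataset")
    from .reconstruct import km_at  # local import avoids a cycle at module load

    t_max = float(np.max(ipd.times))
    grid = np.arange(0.0, t_max + grid_step / 2, grid_step)
    if grid[-1] < t_max:
        grid = np.append(grid, t_max)
    s = km_at(ipd, grid)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        s = s + rng.uniform(-jitter, jitter, size=s.shape)
        s = np.minimum.accumulate(np.clip(s, 0.0, 1.0))
    s[0] = 1.0

    risk_times = np.arange(0.0, t_max + 1e-9, risk_interval)
    times = ipd.times
    risk = [(float(rt), int(np.sum(times >= rt))) for rt in risk_times]
    risk = [(rt, n) for rt, n in risk if n > 0]
    return DigitizedKM(
        points=tuple(zip(grid.tolist(), s.tolist())),
        risk_table=tuple(risk),
    )


# ---------------------------------------------------------------------------
# fixture model configurations
# ---------------------------------------------------------------------------

#: Spline knots are not published.  For the scenario-A progression curve the
#: knots below make the published coefficients yield a valid monotone curve
#: whose median matches the trial's 3.6 months; for the scenario-B overall
#: survival spline no knot placement keeps the published coefficients both
#: monotone and plausible, so a generic log-month placeholder is used and the
#: engine's monotone clamp governs (documented limitation).
RP_KNOTS_A_PFS = (-1.8627, -1.4112, -1.0743, -0.4131)
PLACEHOLDER_RP_KNOTS = (
    math.log(0.5), math.log(3.0), math.log(8.0), math.log(20.0)
)

#: Salvage-regimen mix after progression is a documented placeholder
#: (proportions unpublished; monthly costs are the published unit costs).
PLACEHOLDER_SUBSEQUENT_MIX = (
    SubsequentRegimen("docetaxel", 0.40, 1_462.0),
    SubsequentRegimen("enzalutamide", 0.20, 9_821.0),
    SubsequentRegimen("abiraterone", 0.20, 9_597.0),
    SubsequentRegimen("cabazitaxel", 0.20, 14_864.0),
)

PLACEHOLDER_SUBSEQUENT_DURATION_MONTHS = 6.0

#: Published per-event management costs and the grade>=3 disutility; event
#: probabilities are unpublished, so the zero-default profile contributes
#: nothing and the "test" profile uses round placeholder rates.
_AE_TABLE = (
    ("vomiting", 2_638.0, 0.16, 3.0),
    ("backpain", 11_815.0, 0.16, 3.0),
    ("anemia", 145.0, 0.16, 3.0),
    ("fatigue", 858.0, 0.16, 3.0),
)
_AE_TEST_PROBABILITIES = {"vomiting": 0.02, "backpain": 0.07, "anemia": 0.22, "fatigue": 0.03}

OLAPARIB_DAILY_COST = 246.80
ENZALUTAMIDE_WEEKLY_COST = 2_559.0
ABIRATERONE_WEEKLY_COST = 2_395.0
P_ENZALUTAMIDE = 0.54

_SURVIVAL_MODELS = {
    "A": {
        "standard_care": {
            "pfs": dict(
                family="rp_spline",
                params={"gamma0": 3.965, "gamma1": 5.800, "gamma2": 2.247, "gamma3": 1.103},
                knots=RP_KNOTS_A_PFS,
            ),
            "os": dict(family="gamma", params={"shape": 2.1689, "rate": 0.1485}),
        },
        "olaparib": {
            "pfs": dict(
                family="mixture_cure",
                params={"theta": 0.097, "shape": 2.383, "scale": 2.889},
                base_family="loglogistic",
            ),
            "os": dict(family="gompertz", params={"shape": 0.06804, "rate": 0.01423}),
        },
        "hr_pfs": (0.34, 0.25, 0.47),
        "hr_os": (0.64, 0.43, 0.97),
    },
    "B": {
        "standard_care": {
            "pfs": dict(
                family="nonmixture_cure",
                params={"theta": 0.223, "meanlog": 1.206, "sdlog": 0.633},
                base_family="lognormal",
            ),
            "os": dict(family="gamma", params={"shape": 2.0877, "rate": 0.1387}),
        },
        "olaparib": {
            "pfs": dict(family="gamma", params={"shape": 1.540, "rate": 0.161}),
            "os": dict(
                family="rp_spline",
                params={"gamma0": 4.838, "gamma1": 0.887, "gamma2": 0.873, "gamma3": 1.294},
                knots=PLACEHOLDER_RP_KNOTS,
            ),
        },
        "hr_pfs": (0.49, 0.38, 0.63),
        "hr_os": (0.67, 0.49, 0.93),
    },
}

#: Extrapolation switches to HR carry-forward after the observed follow-up
#: (PFS 18 months, OS 24 months) in the tested arm.
EXTRAPOLATION_CUTOFFS_MONTHS = (18.0, 24.0)


def _dist(spec: dict) -> SurvivalDistribution:
    return SurvivalDistribution(
        family=spec["family"],
        params=spec["params"],
        time_unit="months",
        knots=spec.get("knots"),
        base_family=spec.get("base_family"),
    )


def _ae_events(profile: str) -> tuple[AdverseEvent, ...]:
    if profile == "zero":
        probs = {label: 0.0 for label, *_ in _AE_TABLE}
    elif profile == "test":
        probs = _AE_TEST_PROBABILITIES
    else:
        raise ValidationError(f"unknown AE profile {profile!r}")
    return tuple(
        AdverseEvent(label, probs[label], cost, disutility, duration)
        for label, cost, disutility, duration in _AE_TABLE
    )


def make_fixture_config(
    scenario_label: str = "A",
    ae_profile: str = "zero",
    ngs_mode: str = "flat",
    horizon_weeks: float = 520.0,
) -> ScenarioModel:
    """Complete two-strategy model populated with the published inputs.

    Unpublished inputs (spline knots, adverse-event incidences, salvage mix
    and duration) carry documented placeholder defaults.
    """
    if scenario_label not in _SURVIVAL_MODELS:
        raise ValidationError("scenario_label must be 'A' or 'B'")
    spec = _SURVIVAL_MODELS[scenario_label]

    sc_weekly = P_ENZALUTAMIDE * ENZALUTAMIDE_WEEKLY_COST + (1 - P_ENZALUTAMIDE) * ABIRATERONE_WEEKLY_COST
    shared = dict(
        subsequent_mix=PLACEHOLDER_SUBSEQUENT_MIX,
        subsequent_duration_months=PLACEHOLDER_SUBSEQUENT_DURATION_MONTHS,
        supportive_care_cost_per_day=190.0,
        followup_cost_per_week=146.0,
        terminal_cost=36_403.0,
        price_discount=0.15,
        drug_cost_is_net=False,  # published prices are list prices; 15% applied at accrual
        ae_events=_ae_events(ae_profile),
    )

    reference = StrategyConfig(
        name="standard_care",
        pfs_model=_dist(spec["standard_care"]["pfs"]),
        os_model=_dist(spec["standard_care"]["os"]),
        weekly_drug_cost=sc_weekly,
        p_subsequent_active=0.634,
        **shared,
    )
    intervention = StrategyConfig(
        name="olaparib",
        pfs_model=_dist(spec["olaparib"]["pfs"]),
        os_model=_dist(spec["olaparib"]["os"]),
        weekly_drug_cost=OLAPARIB_DAILY_COST * 7.0,
        p_subsequent_active=0.352,
        hr_pfs=RatioCI(*spec["hr_pfs"]),
        hr_os=RatioCI(*spec["hr_os"]),
        extrapolation_cutoffs=EXTRAPOLATION_CUTOFFS_MONTHS,
        ngs=NGSConfig(
            test_cost=benchmarks.NGS_TEST_COST,
            prevalence=benchmarks.PREVALENCE[scenario_label],
            mode=ngs_mode,
        ),
        **shared,
    )
    settings = ModelSettings(horizon_weeks=horizon_weeks)
    return ScenarioModel(
        reference=reference,
        intervention=intervention,
        settings=settings,
        label=scenario_label,
    )


def default_param_specs(model: ScenarioModel) -> list[ParamSpec]:
    """Sensitivity specs mirroring the published parameter table.

    Published distribution parameters are attached as overrides where given;
    other rows derive their distribution from (base, range).  The fixed
    intervention drug price is sampled as fixed in PSA but still varied over
    its published range in one-way analysis.
    """
    scen = model.label or "A"
    hr_pfs = model.intervention.hr_pfs
    hr_os = model.intervention.hr_os
    sc_weekly = model.reference.weekly_drug_cost
    ola_weekly = model.intervention.weekly_drug_cost
    specs = [
        ParamSpec("hr_pfs", "intervention.hr_pfs.value",
                  hr_pfs.value, hr_pfs.low, hr_pfs.high, "lognormal"),
        ParamSpec("hr_os", "intervention.hr_os.value",
                  hr_os.value, hr_os.low, hr_os.high, "lognormal"),
        ParamSpec("u_pfd", "settings.u_pfd", 0.76, 0.65, 0.87, "beta"),
        ParamSpec("u_pd", "settings.u_pd", 0.37, 0.33, 0.41, "beta"),
        ParamSpec("p_subsequent_standard_care", "reference.p_subsequent_active",
                  0.634, 0.476, 0.793, "beta", dist_params=(5.9, 3.4)),
        ParamSpec("p_subsequent_olaparib", "intervention.p_subsequent_active",
                  0.352, 0.264, 0.44, "beta", dist_params=(10.4, 19.1)),
        ParamSpec("weekly_cost_olaparib", "intervention.weekly_drug_cost",
                  ola_weekly, 123.4 * 7, 246.8 * 7, "fixed"),
        ParamSpec("weekly_cost_standard_care", "reference.weekly_drug_cost",
                  sc_weekly, sc_weekly * 0.9, sc_weekly * 1.1, "gamma"),
        ParamSpec("supportive_care_per_day",
                  ("reference.supportive_care_cost_per_day",
                   "intervention.supportive_care_cost_per_day"),
                  190.0, 142.0, 237.0, "gamma", dist_params=(4.0, 49.921)),
        ParamSpec("terminal_care",
                  ("reference.terminal_cost", "intervention.terminal_cost"),
                  36_403.0, 27_117.0, 45_689.0, "gamma", dist_params=(142_757.0, 0.255)),
        ParamSpec("followup_per_week",
                  ("reference.followup_cost_per_week",
                   "intervention.followup_cost_per_week"),
                  146.0, 109.0, 182.0, "gamma", dist_params=(591.0, 0.247)),
        ParamSpec("ngs_test_cost", "intervention.ngs.test_cost",
                  benchmarks.NGS_TEST_COST,
                  benchmarks.NGS_TEST_COST * 0.75, benchmarks.NGS_TEST_COST * 1.25,
                  "gamma"),
    ]
    return specs
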
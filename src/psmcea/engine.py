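"""Weekly-cycle partitioned-survival engine with screening costs.

State occupancy is read directly off the endpoint curves: alive = S_OS(t),
progression-free = min(S_PFS, S_OS), progressed = alive - progression-free,
dead = 1 - alive.  Costs and QALYs accrue per cycle with continuous-time
discounting; intervention-arm tails can be extrapolated by carrying the
reference arm's hazard forward under a hazard ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, ExtrapolationError, ParameterDomainError
from .survival import SurvivalDistribution, survival_at

logger = logging.getLogger(__name__)

WEEKS_PER_MONTH = 365.25 / 84.0      # exact calendar conversion
WEEKS_PER_YEAR = 52.1775
DAYS_PER_WEEK = 7.0

_SF_CACHE: dict[tuple, np.ndarray] = {}
_SF_CACHE_MAX = 256


def _to_native(t_weeks: np.ndarray, time_unit: str) -> np.ndarray:
    if time_unit == "weeks":
        return t_weeks
    if time_unit == "months":
        return t_weeks / WEEKS_PER_MONTH
    if time_unit == "years":
        return t_weeks / WEEKS_PER_YEAR
    raise ConfigError(f"unknown time_unit {time_unit!r}")


def survival_weeks(dist: SurvivalDistribution, t_weeks: np.ndarray) -> np.ndarray:
    """S(t) evaluated on a weekly grid, memoized on (distribution, grid)."""
    t_weeks = np.asarray(t_weeks, float)
    key = (dist.key(), t_weeks.shape, float(t_weeks[0]), float(t_weeks[-1]), len(t_weeks))
    hit = _SF_CACHE.get(key)
    if hit is not None:
        return hit
    s = survival_at(dist, _to_native(t_weeks, dist.time_unit))
    s = np.minimum.accumulate(np.clip(np.asarray(s, float), 0.0, 1.0))
    if len(_SF_CACHE) >= _SF_CACHE_MAX:
        _SF_CACHE.clear()
    _SF_CACHE[key] = s
    return s


def adjusted_survival(
    own: SurvivalDistribution,
    reference: SurvivalDistribution,
    hr: float,
    cutoff: float,
    t,
):
    """Own curve up to ``cutoff``, then proportional-hazards carry-forward.

    For t > cutoff: S_own(cutoff) * (S_ref(t) / S_ref(cutoff)) ** hr.
    Times are in the distributions' shared native unit; the branches agree at
    the cutoff, so the curve is continuous.
    """
    if hr <= 0:
        raise ParameterDomainError("hazard ratio must be positive")
    if own.time_unit != reference.time_unit:
        raise ConfigError("own and reference distributions must share a time unit")
    t_arr = np.atleast_1d(np.asarray(t, float))
    s_own = np.asarray(survival_at(own, t_arr), float)
    s_ref_cut = float(survival_at(reference, cutoff))
    if s_ref_cut <= 0:
        raise ExtrapolationError("reference survival is 0 at the cutoff")
    s_own_cut = float(survival_at(own, cutoff))
    s_ref = np.asarray(survival_at(reference, t_arr), float)
    tail = s_own_cut * np.power(s_ref / s_ref_cut, hr)
    out = np.where(t_arr > cutoff, tail, s_own)
    return float(out[0]) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class RatioCI:
    """Point estimate with a 95% interval.

    The value may sit outside [low, high] after probabilistic resampling;
    only positivity and interval ordering are enforced.
    """

    value: float
    low: float
    high: float

    def __post_init__(self):
        if self.value <= 0 or self.low <= 0:
            raise ConfigError(f"ratios must be positive: {self}")
        if self.low > self.high:
            raise ConfigError(f"ratio interval must satisfy low <= high: {self}")


@dataclass(frozen=True)
class AdverseEvent:
    label: str
    probability: float
    cost: float
    disutility: float
    duration_weeks: float

    def __post_init__(self):
        if not 0 <= self.probability <= 1:
            raise ConfigError(f"AE probability out of [0,1]: {self.label}")
        if self.cost < 0 or self.disutility < 0 or self.duration_weeks < 0:
            raise ConfigError(f"AE fields must be non-negative: {self.label}")


@dataclass(frozen=True)
class SubsequentRegimen:
    label: str
    proportion: float
    monthly_cost: float


@dataclass(frozen=True)
class NGSConfig:
    """Companion-diagnostic screening cost attached to the tested strategy."""

    test_cost: float = 5800.0
    prevalence: float = 1.0
    mode: str = "flat"  # or "per_screened"

    def __post_init__(self):
        if self.test_cost < 0:
            raise ConfigError("test_cost must be >= 0")
        if not 0 < self.prevalence <= 1:
            raise ConfigError("prevalence must lie in (0, 1]")
        if self.mode not in ("flat", "per_screened"):
            raise ConfigError(f"unknown screening mode {self.mode!r}")


def nns(prevalence: float) -> float:
    """Number needed to screen per eligible patient, to one decimal."""
    if not 0 < prevalence <= 1:
        raise ParameterDomainError("prevalence must lie in (0, 1]")
    return round(1.0 / prevalence, 1)


def screening_cost(test_cost: float, prevalence: float, mode: str = "flat") -> float:
    """Screening cost attributed to each treated patient."""
    if test_cost < 0:
        raise ParameterDomainError("test_cost must be >= 0")
    if mode == "flat":
        return float(test_cost)
    if mode == "per_screened":
        return float(test_cost) * nns(prevalence)
    raise ParameterDomainError(f"unknown screening mode {mode!r}")


@dataclass(frozen=True)
class StrategyConfig:
    """One arm's clinical, cost and utility inputs."""

    name: str
    pfs_model: SurvivalDistribution
    os_model: SurvivalDistribution
    weekly_drug_cost: float
    p_subsequent_active: float
    subsequent_mix: tuple[SubsequentRegimen, ...]
    subsequent_duration_months: float
    supportive_care_cost_per_day: float
    followup_cost_per_week: float
    terminal_cost: float
    hr_pfs: Optional[RatioCI] = None
    hr_os: Optional[RatioCI] = None
    extrapolation_cutoffs: Optional[tuple[float, float]] = None  # native unit (pfs, os)
    price_discount: float = 0.15
    drug_cost_is_net: bool = True  # False: apply price_discount at accrual
    ae_events: tuple[AdverseEvent, ...] = ()
    ngs: Optional[NGSConfig] = None

    def __post_init__(self):
        object.__setattr__(self, "subsequent_mix", tuple(self.subsequent_mix))
        object.__setattr__(self, "ae_events", tuple(self.ae_events))
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.p_subsequent_active <= 1:
            raise ConfigError("p_subsequent_active must lie in [0,1]")
        if not 0 <= self.price_discount < 1:
            raise ConfigError("price_discount must lie in [0,1)")
        for c in (
            self.weekly_drug_cost, self.supportive_care_cost_per_day,
            self.followup_cost_per_week, self.terminal_cost,
            self.subsequent_duration_months,
        ):
            if c < 0:
                raise ConfigError("costs and durations must be >= 0")
        if self.subsequent_mix:
            tot = sum(r.proportion for r in self.subsequent_mix)
            if abs(tot - 1.0) > 1e-9:
                raise ConfigError(f"subsequent_mix proportions must sum to 1, got {tot}")
            if any(r.monthly_cost < 0 or r.proportion < 0 for r in self.subsequent_mix):
                raise ConfigError("subsequent_mix entries must be non-negative")
        if self.extrapolation_cutoffs is not None:
            if any(c <= 0 for c in self.extrapolation_cutoffs):
                raise ConfigError("extrapolation cutoffs must be positive")

    @property
    def effective_weekly_drug_cost(self) -> float:
        if self.drug_cost_is_net:
            return self.weekly_drug_cost
        return self.weekly_drug_cost * (1.0 - self.price_discount)

    @property
    def subsequent_monthly_cost(self) -> float:
        return sum(r.proportion * r.monthly_cost for r in self.subsequent_mix)


@dataclass(frozen=True)
class ModelSettings:
    """Global model settings shared by both strategies."""

    horizon_weeks: float = 520.0
    cycle_length_weeks: float = 1.0
    annual_discount: float = 0.03
    u_pfd: float = 0.76
    u_pd: float = 0.37
    wtp: float = 150_000.0
    half_cycle_correction: bool = False

    def __post_init__(self):
        if not (0 <= self.u_pfd <= 1 and 0 <= self.u_pd <= 1):
            raise ConfigError("utilities must lie in [0,1]")
        if self.horizon_weeks < self.cycle_length_weeks:
            raise ConfigError("horizon must cover at least one cycle")
        if self.annual_discount < 0:
            raise ConfigError("discount rate must be >= 0")
        if self.cycle_length_weeks <= 0:
            raise ConfigError("cycle length must be positive")


@dataclass(frozen=True)
class Trace:
    """Per-cycle state occupancy with discounted accruals and totals."""

    time_weeks: np.ndarray
    p_pfd: np.ndarray
    p_pd: np.ndarray
    p_dead: np.ndarray
    cost: np.ndarray      # discounted $ accrued in each cycle
    qaly: np.ndarray      # discounted QALYs accrued in each cycle
    total_cost: float
    total_qalys: float
    total_lys: float
    cost_in_pfd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_weeks": self.time_weeks,
            "p_pfd": self.p_pfd,
            "p_pd": self.p_pd,
            "p_dead": self.p_dead,
            "disc_cost": self.cost,
            "disc_qaly": self.qaly,
        })

    def summary(self) -> dict:
        return {
            "total_cost": float(self.total_cost),
            "cost_in_pfd": float(self.cost_in_pfd),
            "total_lys": float(self.total_lys),
            "total_qalys": float(self.total_qalys),
        }


def _curve_weeks(
    own: SurvivalDistribution,
    reference: Optional[SurvivalDistribution],
    hr: Optional[float],
    cutoff_native: Optional[float],
    t_weeks: np.ndarray,
) -> np.ndarray:
    s_own = survival_weeks(own, t_weeks)
    if reference is None or hr is None or cutoff_native is None:
        return s_own
    cutoff_weeks = cutoff_native * (
        WEEKS_PER_MONTH if own.time_unit == "months"
        else WEEKS_PER_YEAR if own.time_unit == "years" else 1.0
    )
    s_ref = survival_weeks(reference, t_weeks)
    s_ref_cut = float(survival_at(reference, cutoff_native))
    if s_ref_cut <= 0:
        raise ExtrapolationError("reference survival is 0 at the extrapolation cutoff")
    s_own_cut = float(survival_at(own, cutoff_native))
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = s_own_cut * np.power(np.maximum(s_ref, 0.0) / s_ref_cut, hr)
    s = np.where(t_weeks > cutoff_weeks, tail, s_own)
    return np.minimum.accumulate(np.clip(s, 0.0, 1.0))


def build_trace(
    strategy: StrategyConfig,
    settings: ModelSettings,
    reference: Optional[StrategyConfig] = None,
) -> Trace:
    """Run the partitioned-survival model for one strategy.

    ``reference`` supplies the curves used for hazard-ratio carry-forward
    beyond the strategy's extrapolation cutoffs (if configured).

    Accrual conventions: state costs and utilities accrue on cycle-start
    occupancy; subsequent-therapy cost is a lump sum per new progression
    (regimen mix x monthly cost x duration); terminal cost is a lump sum per
    new death; screening and adverse-event costs land in the first cycle.
    """
    dt = settings.cycle_length_weeks
    n = int(np.ceil(settings.horizon_weeks / dt))
    edges = np.arange(n + 1, dtype=float) * dt  # cycle boundaries in weeks

    cutoffs = strategy.extrapolation_cutoffs
    ref_pfs = reference.pfs_model if (reference is not None and cutoffs) else None
    ref_os = reference.os_model if (reference is not None and cutoffs) else None
    if cutoffs and reference is None:
        logger.warning("extrapolation cutoffs set but no reference arm given; ignored")
    if cutoffs and cutoffs[1] * WEEKS_PER_MONTH > settings.horizon_weeks:
        logger.warning("horizon is shorter than the extrapolation cutoff")

    hr_pfs = strategy.hr_pfs.value if strategy.hr_pfs else None
    hr_os = strategy.hr_os.value if strategy.hr_os else None
    s_os_e = _curve_weeks(
        strategy.os_model, ref_os, hr_os, cutoffs[1] if cutoffs else None, edges
    )
    s_pfs_e = _curve_weeks(
        strategy.pfs_model, ref_pfs, hr_pfs, cutoffs[0] if cutoffs else None, edges
    )
    p_pfd_e = np.minimum(s_pfs_e, s_os_e)  # OS clamp

    # cycle-start occupancy
    p_alive = s_os_e[:-1]
    p_pfd = p_pfd_e[:-1]
    p_pd = p_alive - p_pfd
    p_dead = 1.0 - p_alive
    if settings.half_cycle_correction:
        p_alive = 0.5 * (s_os_e[:-1] + s_os_e[1:])
        p_pfd = 0.5 * (p_pfd_e[:-1] + p_pfd_e[1:])
        p_pd = p_alive - p_pfd
        p_dead = 1.0 - p_alive

    new_dead = s_os_e[:-1] - s_os_e[1:]
    new_pd = np.clip(p_pfd_e[:-1] - p_pfd_e[1:], 0.0, None)

    t_start = edges[:-1]
    df = np.power(1.0 + settings.annual_discount, -t_start / WEEKS_PER_YEAR)
    years = dt / WEEKS_PER_YEAR

    qaly = (p_pfd * settings.u_pfd + p_pd * settings.u_pd) * years * df
    ae_disutility = sum(
        ae.probability * ae.disutility * (ae.duration_weeks / WEEKS_PER_YEAR)
        for ae in strategy.ae_events
    )
    qaly[0] -= ae_disutility * df[0]

    drug = strategy.effective_weekly_drug_cost * dt * p_pfd
    followup = strategy.followup_cost_per_week * dt * (p_pfd + p_pd)
    followup_pfd = strategy.followup_cost_per_week * dt * p_pfd
    supportive = (
        strategy.supportive_care_cost_per_day * DAYS_PER_WEEK * dt
        * p_pd * (1.0 - strategy.p_subsequent_active)
    )
    subsequent = (
        new_pd * strategy.p_subsequent_active
        * strategy.subsequent_monthly_cost * strategy.subsequent_duration_months
    )
    terminal = new_dead * strategy.terminal_cost

    cost = (drug + followup + supportive + subsequent + terminal) * df
    cost_pfd = (drug + followup_pfd) * df

    ae_cost = sum(ae.probability * ae.cost for ae in strategy.ae_events)
    cost[0] += ae_cost * df[0]
    cost_pfd[0] += ae_cost * df[0]
    if strategy.ngs is not None:
        ngs_cost = screening_cost(
            strategy.ngs.test_cost, strategy.ngs.prevalence, strategy.ngs.mode
        )
        cost[0] += ngs_cost * df[0]
        cost_pfd[0] += ngs_cost * df[0]

    lys = float(np.sum(p_alive * years * df))
    return Trace(
        time_weeks=t_start,
        p_pfd=p_pfd,
        p_pd=p_pd,
        p_dead=p_dead,
        cost=cost,
        qaly=qaly,
        total_cost=float(np.sum(cost)),
        total_qalys=float(np.sum(qaly)),
        total_lys=lys,
        cost_in_pfd=float(np.sum(cost_pfd)),
    )
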
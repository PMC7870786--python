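"""Deterministic and probabilistic uncertainty analysis.

Covers the distribution-derivation rules used to turn (mean, range) rows into
sampling distributions, one-way sensitivity analysis (tornado table),
Monte-Carlo probabilistic sensitivity analysis, cost-effectiveness
acceptability curves, and hazard-ratio-driven subgroup analysis.

Derivation conventions
----------------------
* beta: sd = (high - low)/3.92, total = m(1-m)/sd^2 (no -1 correction),
  alpha = m*total, beta = (1-m)*total.
* lognormal: meanlog = ln(point), sdlog = ln(high/low)/3.92.
* gamma: method of moments, shape = mean^2/sd^2, scale = sd^2/mean; published
  (shape, scale) pairs can be passed as overrides (mean = shape*scale).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .econ import CEResult
from .exceptions import ParameterDomainError, ValidationError
from .model import ScenarioModel, get_path

logger = logging.getLogger(__name__)

DIST_FAMILIES = ("beta", "gamma", "lognormal", "fixed")


# ---------------------------------------------------------------------------
# distribution derivation from (mean, range) rows
# ---------------------------------------------------------------------------

def derive_beta(mean: float, low: float, high: float) -> tuple[float, float]:
    """Beta (alpha, beta) by method of moments from a mean and 95% range."""
    if not 0 < mean < 1:
        raise ParameterDomainError("beta mean must lie strictly in (0, 1)")
    if not (0 <= low < high <= 1):
        raise ParameterDomainError("beta range must satisfy 0 <= low < high <= 1")
    sd = (high - low) / 3.92
    total = mean * (1.0 - mean) / sd**2
    return mean * total, (1.0 - mean) * total


def derive_lognormal(point: float, low: float, high: float) -> tuple[float, float]:
    """Lognormal (meanlog, sdlog) from a ratio point estimate and 95% CI."""
    if point <= 0 or low <= 0 or high <= 0:
        raise ParameterDomainError("lognormal inputs must be positive")
    if not (low <= point <= high):
        raise ParameterDomainError("CI must bracket the point estimate")
    return math.log(point), math.log(high / low) / 3.92


def derive_gamma(mean: float, low: float, high: float) -> tuple[float, float]:
    """Gamma (shape, scale) by method of moments from a mean and 95% range."""
    if mean <= 0:
        raise ParameterDomainError("gamma mean must be positive")
    if not low < high:
        raise ParameterDomainError("need low < high")
    sd = (high - low) / 3.92
    shape = mean**2 / sd**2
    scale = sd**2 / mean
    return shape, scale


def gamma_mean(shape: float, scale: float) -> float:
    """Mean implied by a printed (shape, scale) gamma override."""
    if shape <= 0 or scale <= 0:
        raise ParameterDomainError("gamma parameters must be positive")
    return shape * scale


# ---------------------------------------------------------------------------
# parameter specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, range, sampling distribution.

    ``path`` is the dotted model path (or several paths, all set to the same
    sampled value — used when both arms share a unit cost).  ``dist_params``
    overrides the derived distribution with published parameters:
    beta -> (alpha, beta); gamma -> (shape, scale); lognormal ->
    (meanlog, sdlog).
    """

    name: str
    path: Union[str, tuple[str, ...]]
    base: float
    low: float
    high: float
    dist_family: str = "fixed"
    dist_params: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.dist_family not in DIST_FAMILIES:
            raise ValidationError(f"unknown distribution family {self.dist_family!r}")
        if not self.low <= self.base <= self.high:
            raise ValidationError(
                f"{self.name}: range [{self.low}, {self.high}] must bracket base {self.base}"
            )

    @property
    def paths(self) -> tuple[str, ...]:
        return (self.path,) if isinstance(self.path, str) else tuple(self.path)

    def resolved_dist(self) -> tuple[str, tuple[float, float] | None]:
        """(family, parameters) actually used for sampling."""
        if self.dist_family == "fixed":
            return "fixed", None
        if self.dist_params is not None:
            return self.dist_family, self.dist_params
        if self.dist_family == "beta":
            return "beta", derive_beta(self.base, self.low, self.high)
        if self.dist_family == "gamma":
            return "gamma", derive_gamma(self.base, self.low, self.high)
        return "lognormal", derive_lognormal(self.base, self.low, self.high)

    def sample(self, rng: np.random.Generator, max_redraws: int = 100) -> float:
        family, params = self.resolved_dist()
        if family == "fixed":
            return self.base
        redraws = 0
        while True:
            if family == "beta":
                v = float(rng.beta(params[0], params[1]))
                ok = 0.0 < v < 1.0
            elif family == "gamma":
                v = float(rng.gamma(params[0], params[1]))
                ok = v > 0.0 and np.isfinite(v)
            else:  # lognormal
                v = float(rng.lognormal(params[0], params[1]))
                ok = v > 0.0 and np.isfinite(v)
            if ok:
                if redraws:
                    logger.warning("%s: %d invalid draws redrawn", self.name, redraws)
                return v
            redraws += 1
            if redraws > max_redraws:
                raise ValidationError(f"{self.name}: could not draw a valid value")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "path": list(self.paths) if len(self.paths) > 1 else self.paths[0],
            "base": self.base,
            "low": self.low,
            "high": self.high,
            "dist_family": self.dist_family,
        }
        if self.dist_params is not None:
            d["dist_params"] = list(self.dist_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParamSpec":
        path = d["path"]
        return cls(
            name=d["name"],
            path=tuple(path) if isinstance(path, list) else path,
            base=float(d["base"]),
            low=float(d["low"]),
            high=float(d["high"]),
            dist_family=d.get("dist_family", "fixed"),
            dist_params=tuple(d["dist_params"]) if d.get("dist_params") else None,
        )


def _apply(model: ScenarioModel, spec: ParamSpec, value: float) -> ScenarioModel:
    for p in spec.paths:
        model = model.with_param(p, value)
    return model


def _outcome(result: CEResult, outcome: str) -> float:
    if outcome == "inhb":
        return result.inhb
    if outcome == "inmb":
        return result.inmb
    if outcome == "icer":
        return result.icer if isinstance(result.icer, float) else float("nan")
    raise ValidationError(f"unknown outcome {outcome!r}")


# ---------------------------------------------------------------------------
# one-way sensitivity analysis
# ---------------------------------------------------------------------------

def one_way(
    model: ScenarioModel,
    specs: Sequence[ParamSpec],
    outcome: str = "inhb",
) -> pd.DataFrame:
    """Tornado table: outcome at each parameter's low/high, others at base.

    Rows are sorted by |outcome_high - outcome_low| descending; a model
    failure at an extreme is recorded (``failed=True``), not raised.
    """
    base_value = _outcome(model.evaluate(), outcome)
    rows = []
    for spec in sorted(specs, key=lambda s: s.name):
        row = {"parameter": spec.name, "base": base_value, "failed": False}
        try:
            row["outcome_low"] = _outcome(_apply(model, spec, spec.low).evaluate(), outcome)
            row["outcome_high"] = _outcome(_apply(model, spec, spec.high).evaluate(), outcome)
            row["span"] = abs(row["outcome_high"] - row["outcome_low"])
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("one_way: %s failed at an extreme: %s", spec.name, exc)
            row.update(outcome_low=np.nan, outcome_high=np.nan, span=np.nan, failed=True)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        "span", ascending=False, kind="stable", na_position="last"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSASample:
    """One Monte-Carlo iteration: drawn parameter values and its CE result."""

    iteration: int
    params: dict
    result: CEResult


def psa(
    model: ScenarioModel,
    specs: Sequence[ParamSpec],
    n_iter: int = 10_000,
    seed: int = 0,
) -> list[PSASample]:
    """Joint independent draws evaluated through the model; seed-reproducible."""
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    samples = []
    for it in range(n_iter):
        drawn = {spec.name: spec.sample(rng) for spec in specs}
        m = model
        for spec in specs:
            m = _apply(m, spec, drawn[spec.name])
        samples.append(PSASample(iteration=it, params=drawn, result=m.evaluate()))
    return samples


def psa_frame(samples: Iterable[PSASample]) -> pd.DataFrame:
    """Per-iteration (delta cost, delta effect, INHB, INMB) table."""
    return pd.DataFrame(
        {
            "iteration": s.iteration,
            "delta_cost": s.result.delta_cost,
            "delta_effect": s.result.delta_effect,
            "inhb": s.result.inhb,
            "inmb": s.result.inmb,
        }
        for s in samples
    )


def ceac(
    samples: Sequence[PSASample],
    wtp_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """P(cost-effective) = P(INMB(lambda) > 0) on a willingness-to-pay grid."""
    if wtp_grid is None:
        wtp_grid = np.arange(0, 300_001, 5_000, dtype=float)
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValidationError("wtp grid must be non-empty")
    if len(samples) == 0:
        raise ValidationError("need at least one PSA sample")
    dc = np.array([s.result.delta_cost for s in samples])
    de = np.array([s.result.delta_effect for s in samples])
    prob = [(de * lam - dc > 0).mean() for lam in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})


def prob_cost_effective(samples: Sequence[PSASample], wtp: float) -> float:
    dc = np.array([s.result.delta_cost for s in samples])
    de = np.array([s.result.delta_effect for s in samples])
    return float((de * wtp - dc > 0).mean())


# ---------------------------------------------------------------------------
# subgroup analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubgroupResult:
    label: str
    hr_point: float
    hr_low: float
    hr_high: float
    inhb_point: float
    inhb_range: tuple[float, float]
    prob_cost_effective: float


HR_PFS_PATH = "intervention.hr_pfs.value"


def subgroup(
    model: ScenarioModel,
    hr_pfs_point: float,
    hr_pfs_range: tuple[float, float],
    specs: Sequence[ParamSpec] = (),
    n_iter: int = 10_000,
    seed: int = 0,
    label: str = "",
) -> SubgroupResult:
    """Deterministic INHB at the subgroup's PFS hazard ratio point/extremes,
    plus PSA-based probability of cost-effectiveness with the PFS HR
    resampled from the subgroup's lognormal distribution."""
    lo, hi = hr_pfs_range
    if not (0 < lo <= hr_pfs_point <= hi):
        raise ValidationError("hazard-ratio range must bracket the point estimate")
    inhb_point = model.with_param(HR_PFS_PATH, hr_pfs_point).evaluate().inhb
    inhb_lo_hr = model.with_param(HR_PFS_PATH, lo).evaluate().inhb
    inhb_hi_hr = model.with_param(HR_PFS_PATH, hi).evaluate().inhb
    hr_spec = ParamSpec(
        name="hr_pfs_subgroup",
        path=HR_PFS_PATH,
        base=hr_pfs_point,
        low=lo,
        high=hi,
        dist_family="lognormal" if lo < hi else "fixed",
    )
    sub_specs = [s for s in specs if HR_PFS_PATH not in s.paths] + [hr_spec]
    samples = psa(model, sub_specs, n_iter=n_iter, seed=seed)
    return SubgroupResult(
        label=label,
        hr_point=hr_pfs_point,
        hr_low=lo,
        hr_high=hi,
        inhb_point=inhb_point,
        inhb_range=(min(inhb_lo_hr, inhb_hi_hr), max(inhb_lo_hr, inhb_hi_hr)),
        prob_cost_effective=prob_cost_effective(samples, model.settings.wtp),
    )
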
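"""Parametric survival distributions, right-censored MLE fitting and AIC selection.

Families supported: exponential, weibull, gamma, lognormal, loglogistic,
gompertz, generalized_gamma, rp_spline (restricted-cubic-spline model for the
log cumulative hazard on log time), mixture_cure and nonmixture_cure (a cure
fraction wrapped around any non-spline base family).

Conventions
-----------
* gamma uses (shape, rate); weibull and loglogistic use (shape, scale) with
  ``rate = 1/scale`` accepted as an alias; gompertz uses (shape, rate) with
  hazard ``rate * exp(shape * t)``.
* ``scale_on_log=True`` reinterprets a distribution's ``scale`` parameter as
  being stored on the log scale (actual scale = exp(value)).  Published
  parameter tables are sometimes ambiguous on this point, so both readings
  are available.
* rp_spline: ln H(t) = gamma0 + gamma1*x + sum_j gamma_{j+1} v_j(x) with
  x = ln t and v_j the restricted cubic spline basis on the supplied knots
  (log-time scale, 2 boundary + K-2 internal knots, K = number of gammas).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .exceptions import (
    NonIdentifiableError,
    ParameterDomainError,
    SelectionError,
    TimeDomainError,
    UndefinedHazardError,
)

logger = logging.getLogger(__name__)

FAMILIES = (
    "exponential",
    "weibull",
    "gamma",
    "lognormal",
    "loglogistic",
    "gompertz",
    "generalized_gamma",
    "rp_spline",
    "mixture_cure",
    "nonmixture_cure",
)

#: Families that can serve as the kernel of a cure model.
CURE_BASE_FAMILIES = (
    "exponential",
    "weibull",
    "gamma",
    "lognormal",
    "loglogistic",
    "gompertz",
)

_TINY = 1e-300


@dataclass(frozen=True)
class SurvivalDistribution:
    """A parametric survival law: family tag plus named parameters.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    params : mapping of str to float
        Named parameters; see module docstring for conventions.  Cure models
        hold ``theta`` plus the base family's parameters.
    time_unit : {"months", "weeks"}
        Unit of the time axis the parameters refer to.
    knots : sequence of float, optional
        rp_spline only — ordered knots on the log-time scale, one per gamma
        coefficient (2 boundary + internal).
    base_family : str, optional
        Cure models only — the kernel family.
    scale_on_log : bool
        Interpret the ``scale`` entry of ``params`` as log(scale).
    """

    family: str
    params: Mapping[str, float]
    time_unit: str = "months"
    knots: tuple[float, ...] | None = None
    base_family: str | None = None
    scale_on_log: bool = False

    def __post_init__(self):
        object.__setattr__(self, "params", dict(self.params))
        if self.knots is not None:
            object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))
        validate_params(self)

    # frozen dataclass with a dict field is unhashable; expose a cache key
    def key(self) -> tuple:
        return (
            self.family,
            tuple(sorted((k, float(v)) for k, v in self.params.items())),
            self.time_unit,
            self.knots,
            self.base_family,
            self.scale_on_log,
        )

    @property
    def n_params(self) -> int:
        return len(self.params)

    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "params": {k: float(v) for k, v in self.params.items()},
            "time_unit": self.time_unit,
        }
        if self.knots is not None:
            d["knots"] = list(self.knots)
        if self.base_family is not None:
            d["base_family"] = self.base_family
        if self.scale_on_log:
            d["scale_on_log"] = True
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurvivalDistribution":
        return cls(
            family=d["family"],
            params=dict(d["params"]),
            time_unit=d.get("time_unit", "months"),
            knots=tuple(d["knots"]) if d.get("knots") else None,
            base_family=d.get("base_family"),
            scale_on_log=bool(d.get("scale_on_log", False)),
        )


def _pos(params: Mapping[str, float], name: str) -> float:
    v = float(params[name])
    if not np.isfinite(v) or v <= 0:
        raise ParameterDomainError(f"{name} must be positive and finite, got {v}")
    return v


def _get_scale(dist_scale_on_log: bool, params: Mapping[str, float]) -> float:
    """Resolve a scale parameter, honouring rate aliasing and log storage."""
    if "scale" in params:
        s = float(params["scale"])
        if dist_scale_on_log:
            return math.exp(s)
        if s <= 0:
            raise ParameterDomainError(f"scale must be positive, got {s}")
        return s
    if "rate" in params:
        r = _pos(params, "rate")
        return 1.0 / r
    raise ParameterDomainError("need a 'scale' or 'rate' parameter")


def validate_params(dist: SurvivalDistribution) -> None:
    """Raise ParameterDomainError if parameters are outside their domain."""
    fam = dist.family
    p = dist.params
    if fam not in FAMILIES:
        raise ParameterDomainError(f"unknown family {fam!r}")
    if dist.time_unit not in ("months", "weeks", "years"):
        raise ParameterDomainError(f"unknown time_unit {dist.time_unit!r}")
    if fam == "exponential":
        _pos(p, "rate")
    elif fam == "weibull":
        _pos(p, "shape")
        _get_scale(dist.scale_on_log, p)
    elif fam == "gamma":
        _pos(p, "shape")
        _pos(p, "rate")
    elif fam == "lognormal":
        float(p["meanlog"])
        _pos(p, "sdlog")
    elif fam == "loglogistic":
        _pos(p, "shape")
        _get_scale(dist.scale_on_log, p)
    elif fam == "gompertz":
        float(p["shape"])  # may be negative (defective distribution)
        _pos(p, "rate")
    elif fam == "generalized_gamma":
        _pos(p, "shape")
        if float(p["power"]) == 0:
            raise ParameterDomainError("generalized_gamma power must be nonzero")
        _get_scale(dist.scale_on_log, p)
    elif fam == "rp_spline":
        gammas = _rp_gammas(p)
        if dist.knots is None:
            raise ParameterDomainError("rp_spline requires knots (log-time scale)")
        if len(dist.knots) != len(gammas):
            raise ParameterDomainError(
                f"rp_spline needs one knot per coefficient: "
                f"{len(gammas)} gammas but {len(dist.knots)} knots"
            )
        if len(gammas) < 2:
            raise ParameterDomainError("rp_spline needs at least gamma0, gamma1")
        if any(b <= a for a, b in zip(dist.knots, dist.knots[1:])):
            raise ParameterDomainError("rp_spline knots must be strictly increasing")
    elif fam in ("mixture_cure", "nonmixture_cure"):
        theta = float(p["theta"])
        if not 0.0 <= theta <= 1.0:
            raise ParameterDomainError(f"cure fraction theta must lie in [0,1], got {theta}")
        if dist.base_family not in CURE_BASE_FAMILIES:
            raise ParameterDomainError(
                f"cure model base_family must be one of {CURE_BASE_FAMILIES}, "
                f"got {dist.base_family!r}"
            )
        validate_params(_cure_base(dist))


def _rp_gammas(params: Mapping[str, float]) -> list[float]:
    out = []
    i = 0
    while f"gamma{i}" in params:
        out.append(float(params[f"gamma{i}"]))
        i += 1
    if not out:
        raise ParameterDomainError("rp_spline params must be named gamma0, gamma1, ...")
    return out


def _cure_base(dist: SurvivalDistribution) -> SurvivalDistribution:
    base_params = {k: v for k, v in dist.params.items() if k != "theta"}
    return SurvivalDistribution(
        family=dist.base_family,
        params=base_params,
        time_unit=dist.time_unit,
        scale_on_log=dist.scale_on_log,
    )


# ---------------------------------------------------------------------------
# restricted cubic spline basis (log-time, Royston-Parmar style)
# ---------------------------------------------------------------------------

def _rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Columns [1, x, v_1(x), ..., v_{K-2}(x)] for knots k_1 < ... < k_K."""
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(x), x]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        v = (
            np.maximum(x - kj, 0.0) ** 3
            - lam * np.maximum(x - kmin, 0.0) ** 3
            - (1 - lam) * np.maximum(x - kmax, 0.0) ** 3
        )
        cols.append(v)
    return np.column_stack(cols)


def _rcs_basis_deriv(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.zeros_like(x), np.ones_like(x)]
    for kj in knots[1:-1]:
        lam = (kmax - kj) / (kmax - kmin)
        dv = 3 * (
            np.maximum(x - kj, 0.0) ** 2
            - lam * np.maximum(x - kmin, 0.0) ** 2
            - (1 - lam) * np.maximum(x - kmax, 0.0) ** 2
        )
        cols.append(dv)
    return np.column_stack(cols)


def _rp_eta(dist: SurvivalDistribution, t: np.ndarray) -> np.ndarray:
    """log cumulative hazard at t > 0."""
    gammas = np.array(_rp_gammas(dist.params))
    x = np.log(t)
    return _rcs_basis(x, dist.knots) @ gammas


def _rp_eta_deriv(dist: SurvivalDistribution, t: np.ndarray) -> np.ndarray:
    gammas = np.array(_rp_gammas(dist.params))
    x = np.log(t)
    return _rcs_basis_deriv(x, dist.knots) @ gammas


# ---------------------------------------------------------------------------
# log-survival and log-hazard per family
# ---------------------------------------------------------------------------

def _logsf(dist: SurvivalDistribution, t: np.ndarray) -> np.ndarray:
    fam, p = dist.family, dist.params
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if fam == "exponential":
            return -float(p["rate"]) * t
        if fam == "weibull":
            k = float(p["shape"])
            s = _get_scale(dist.scale_on_log, p)
            return -np.power(t / s, k)
        if fam == "gamma":
            return stats.gamma.logsf(t, float(p["shape"]), scale=1.0 / float(p["rate"]))
        if fam == "lognormal":
            return stats.lognorm.logsf(t, float(p["sdlog"]), scale=math.exp(float(p["meanlog"])))
        if fam == "loglogistic":
            a = float(p["shape"])
            s = _get_scale(dist.scale_on_log, p)
            return -np.log1p(np.power(t / s, a))
        if fam == "gompertz":
            a, b = float(p["shape"]), float(p["rate"])
            if abs(a) < 1e-12:
                return -b * t
            return -(b / a) * np.expm1(a * t)
        if fam == "generalized_gamma":
            a = float(p["shape"])
            c = float(p["power"])
            s = _get_scale(dist.scale_on_log, p)
            return stats.gengamma.logsf(t, a, c, scale=s)
        if fam == "rp_spline":
            out = np.where(t > 0, -np.exp(_rp_eta(dist, np.maximum(t, _TINY))), 0.0)
            return out
        if fam == "mixture_cure":
            theta = float(p["theta"])
            base = _cure_base(dist)
            sb = np.exp(_logsf(base, t))
            return np.log(theta + (1 - theta) * sb)
        if fam == "nonmixture_cure":
            theta = float(p["theta"])
            base = _cure_base(dist)
            sb = np.exp(_logsf(base, t))
            if theta == 0.0:
                return np.where(sb >= 1.0, 0.0, -np.inf)
            return math.log(theta) * (1.0 - sb)
    raise ParameterDomainError(f"unknown family {fam!r}")


def _logpdf(dist: SurvivalDistribution, t: np.ndarray) -> np.ndarray:
    """log density f(t) = h(t) S(t); -inf where the density is 0."""
    fam, p = dist.family, dist.params
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        if fam == "exponential":
            r = float(p["rate"])
            return math.log(r) - r * t
        if fam == "weibull":
            k = float(p["shape"])
            s = _get_scale(dist.scale_on_log, p)
            z = t / s
            return math.log(k / s) + (k - 1) * np.log(z) - np.power(z, k)
        if fam == "gamma":
            return stats.gamma.logpdf(t, float(p["shape"]), scale=1.0 / float(p["rate"]))
        if fam == "lognormal":
            return stats.lognorm.logpdf(t, float(p["sdlog"]), scale=math.exp(float(p["meanlog"])))
        if fam == "loglogistic":
            a = float(p["shape"])
            s = _get_scale(dist.scale_on_log, p)
            z = t / s
            return math.log(a / s) + (a - 1) * np.log(z) - 2 * np.log1p(np.power(z, a))
        if fam == "gompertz":
            a, b = float(p["shape"]), float(p["rate"])
            return math.log(b) + a * t + _logsf(dist, t)
        if fam == "generalized_gamma":
            a = float(p["shape"])
            c = float(p["power"])
            s = _get_scale(dist.scale_on_log, p)
            return stats.gengamma.logpdf(t, a, c, scale=s)
        if fam == "rp_spline":
            tt = np.maximum(t, _TINY)
            eta = _rp_eta(dist, tt)
            deta = _rp_eta_deriv(dist, tt)
            out = np.where(
                deta > 0,
                eta + np.log(np.maximum(deta, _TINY)) - np.log(tt) - np.exp(eta),
                -np.inf,
            )
            return out
        if fam == "mixture_cure":
            theta = float(p["theta"])
            base = _cure_base(dist)
            if theta >= 1.0:
                return np.full_like(t, -np.inf)
            return math.log(1 - theta) + _logpdf(base, t)
        if fam == "nonmixture_cure":
            theta = float(p["theta"])
            base = _cure_base(dist)
            if theta <= 0.0 or theta >= 1.0:
                return np.full_like(t, -np.inf)
            # f = -ln(theta) f_base S
            return math.log(-math.log(theta)) + _logpdf(base, t) + _logsf(dist, t)
    raise ParameterDomainError(f"unknown family {fam!r}")


# ---------------------------------------------------------------------------
# public evaluation API
# ---------------------------------------------------------------------------

def survival_at(dist: SurvivalDistribution, t):
    """Survival probability S(t) for scalar or array ``t >= 0``."""
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    flat = np.atleast_1d(arr)
    if np.any(flat < 0):
        raise TimeDomainError("t must be >= 0")
    s = np.exp(_logsf(dist, flat))
    s = np.clip(s, 0.0, 1.0)
    s = np.where(flat == 0.0, 1.0, s)
    return float(s[0]) if scalar else s.reshape(arr.shape)


def hazard_at(dist: SurvivalDistribution, t):
    """Instantaneous hazard h(t) = f(t)/S(t) for ``t > 0``."""
    arr = np.asarray(t, dtype=float)
    scalar = arr.ndim == 0
    flat = np.atleast_1d(arr)
    if np.any(flat <= 0):
        raise TimeDomainError("hazard requires t > 0")
    ls = _logsf(dist, flat)
    if np.any(np.isneginf(ls)) or np.any(np.exp(ls) <= 0):
        raise UndefinedHazardError("S(t) = 0: hazard undefined")
    h = np.exp(_logpdf(dist, flat) - ls)
    return float(h[0]) if scalar else h.reshape(arr.shape)


def cure_fraction_limit(dist: SurvivalDistribution) -> float:
    """lim_{t->inf} S(t) for cure models (theta for mixture form)."""
    theta = float(dist.params["theta"])
    if dist.family == "mixture_cure":
        return theta
    if dist.family == "nonmixture_cure":
        return theta
    raise ParameterDomainError("cure_fraction_limit only defined for cure models")


def inverse_survival(dist: SurvivalDistribution, u) -> np.ndarray:
    """Solve S(t) = u for t; returns inf where u is below the cure plateau.

    Used by the simulator for inverse-transform sampling.  Analytic where
    cheap, bracketed root-finding otherwise.
    """
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any((u_arr <= 0) | (u_arr > 1)):
        raise ParameterDomainError("u must lie in (0, 1]")
    fam, p = dist.family, dist.params

    if fam == "exponential":
        out = -np.log(u_arr) / float(p["rate"])
    elif fam == "weibull":
        k = float(p["shape"])
        s = _get_scale(dist.scale_on_log, p)
        out = s * np.power(-np.log(u_arr), 1.0 / k)
    elif fam == "gamma":
        out = stats.gamma.isf(u_arr, float(p["shape"]), scale=1.0 / float(p["rate"]))
    elif fam == "lognormal":
        out = stats.lognorm.isf(u_arr, float(p["sdlog"]), scale=math.exp(float(p["meanlog"])))
    elif fam == "loglogistic":
        a = float(p["shape"])
        s = _get_scale(dist.scale_on_log, p)
        out = s * np.power(1.0 / u_arr - 1.0, 1.0 / a)
    elif fam == "gompertz":
        a, b = float(p["shape"]), float(p["rate"])
        if abs(a) < 1e-12:
            out = -np.log(u_arr) / b
        else:
            z = 1.0 - (a / b) * np.log(u_arr)
            out = np.where(z > 0, np.log(np.maximum(z, _TINY)) / a, np.inf)
            if a < 0:  # defective: plateau at exp(b/a)
                plateau = math.exp(b / a)
                out = np.where(u_arr <= plateau, np.inf, out)
    elif fam == "generalized_gamma":
        a = float(p["shape"])
        c = float(p["power"])
        s = _get_scale(dist.scale_on_log, p)
        out = stats.gengamma.isf(u_arr, a, c, scale=s)
    elif fam == "mixture_cure":
        theta = float(p["theta"])
        base = _cure_base(dist)
        out = np.where(
            u_arr <= theta,
            np.inf,
            inverse_survival(base, np.clip((u_arr - theta) / (1 - theta), _TINY, 1.0)),
        )
    elif fam == "nonmixture_cure":
        theta = float(p["theta"])
        base = _cure_base(dist)
        if theta >= 1.0:
            out = np.full_like(u_arr, np.inf)
        elif theta <= 0.0:
            out = inverse_survival(base, u_arr)
        else:
            # u = theta^(1 - S_b)  =>  S_b = 1 - ln u / ln theta
            sb = 1.0 - np.log(u_arr) / math.log(theta)
            out = np.where(
                u_arr <= theta, np.inf, inverse_survival(base, np.clip(sb, _TINY, 1.0))
            )
    else:  # rp_spline: numeric inversion on log time
        out = np.empty_like(u_arr)
        for i, ui in enumerate(u_arr):
            target = math.log(-math.log(ui)) if ui < 1.0 else -np.inf
            if ui >= 1.0:
                out[i] = 0.0
                continue

            def g(x, target=target):
                return float(
                    _rp_eta(dist, np.array([math.exp(x)]))[0] - target
                )

            lo, hi = -20.0, 20.0
            if g(lo) > 0:
                out[i] = 0.0
            elif g(hi) < 0:
                out[i] = np.inf
            else:
                out[i] = math.exp(optimize.brentq(g, lo, hi, xtol=1e-12))
    return out if np.ndim(u) else float(out[0])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    """Outcome of a right-censored maximum-likelihood fit."""

    distribution: SurvivalDistribution
    loglik: float
    n_params: int
    aic: float
    converged: bool

    def __post_init__(self):
        if self.converged and not np.isfinite(self.loglik):
            raise ValueError("converged fit must have finite log-likelihood")


def _extract_ipd(ipd) -> tuple[np.ndarray, np.ndarray]:
    """Accept PseudoIPD, (times, events) pair, or a DataFrame with those columns."""
    if hasattr(ipd, "times") and hasattr(ipd, "events"):
        return np.asarray(ipd.times, float), np.asarray(ipd.events, int)
    if hasattr(ipd, "columns"):
        return np.asarray(ipd["time"], float), np.asarray(ipd["event"], int)
    times, events = ipd
    return np.asarray(times, float), np.asarray(events, int)


# free-parameter transforms: name -> (to_free, from_free)
_ID = (lambda v: v, lambda v: v)
_LOG = (math.log, math.exp)


def _logit(x: float) -> float:
    x = min(max(x, 1e-9), 1 - 1e-9)
    return math.log(x / (1 - x))


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


_TRANSFORMS: dict[str, dict[str, tuple[Callable, Callable]]] = {
    "exponential": {"rate": _LOG},
    "weibull": {"shape": _LOG, "scale": _LOG},
    "gamma": {"shape": _LOG, "rate": _LOG},
    "lognormal": {"meanlog": _ID, "sdlog": _LOG},
    "loglogistic": {"shape": _LOG, "scale": _LOG},
    "gompertz": {"shape": _ID, "rate": _LOG},
    "generalized_gamma": {"shape": _LOG, "power": _ID, "scale": _LOG},
}


def _default_init(family: str, times: np.ndarray, events: np.ndarray) -> dict[str, float]:
    """Moment-style starting values; crude but inside the domain."""
    ev_times = times[events == 1]
    mean_t = float(np.mean(ev_times)) if ev_times.size else float(np.mean(times))
    mean_t = max(mean_t, 1e-6)
    rate = max(events.sum() / max(times.sum(), 1e-12), 1e-8)
    if family == "exponential":
        return {"rate": rate}
    if family == "weibull":
        return {"shape": 1.0, "scale": 1.0 / rate}
    if family == "gamma":
        return {"shape": 1.0, "rate": rate}
    if family == "lognormal":
        logs = np.log(np.maximum(ev_times if ev_times.size else times, 1e-12))
        return {"meanlog": float(np.mean(logs)), "sdlog": max(float(np.std(logs)), 0.1)}
    if family == "loglogistic":
        return {"shape": 1.5, "scale": mean_t}
    if family == "gompertz":
        return {"shape": 0.01, "rate": rate}
    if family == "generalized_gamma":
        return {"shape": 1.0, "power": 1.0, "scale": 1.0 / rate}
    raise ParameterDomainError(f"no default init for family {family!r}")


def _make_dist(
    family: str,
    params: dict[str, float],
    time_unit: str,
    knots=None,
    base_family=None,
) -> SurvivalDistribution:
    return SurvivalDistribution(
        family=family,
        params=params,
        time_unit=time_unit,
        knots=knots,
        base_family=base_family,
    )


def _rp_default_knots(times: np.ndarray, events: np.ndarray, n_internal: int = 2):
    """Boundary knots at min/max uncensored log times, internal at centiles."""
    ev = np.log(np.maximum(times[events == 1], 1e-12))
    if ev.size < n_internal + 2:
        raise NonIdentifiableError("too few events to place spline knots")
    qs = np.linspace(0, 100, n_internal + 2)
    knots = np.percentile(ev, qs)
    # nudge apart if degenerate
    for i in range(1, len(knots)):
        if knots[i] <= knots[i - 1]:
            knots[i] = knots[i - 1] + 1e-6
    return tuple(float(k) for k in knots)


def fit_mle(
    family: str,
    ipd,
    init: Mapping[str, float] | None = None,
    *,
    base_family: str | None = None,
    knots: Sequence[float] | None = None,
    time_unit: str = "months",
    n_starts: int = 5,
    seed: int = 12345,
) -> FitResult:
    """Fit one family to right-censored data by maximum likelihood.

    Parameters are optimized on unconstrained transforms (log for positive
    parameters, logit for the cure fraction) with jittered multi-start to
    guard against cure-model multimodality.
    """
    times, events = _extract_ipd(ipd)
    if times.size == 0:
        raise NonIdentifiableError("empty dataset")
    if np.any(times < 0):
        raise TimeDomainError("times must be >= 0")
    if events.sum() < 1:
        raise NonIdentifiableError("no events: parameters are not identifiable")
    times = np.maximum(times, 1e-9)
    is_event = events == 1

    cure = family in ("mixture_cure", "nonmixture_cure")
    if cure and base_family is None:
        raise ParameterDomainError("cure models require base_family")
    kernel = base_family if cure else family

    if family == "rp_spline":
        if knots is None:
            knots = _rp_default_knots(times, events)
            logger.info("rp_spline knots defaulted to log-time centiles: %s", knots)
        knots = tuple(float(k) for k in knots)
        n_gammas = len(knots)
        names = [f"gamma{i}" for i in range(n_gammas)]

        def pack(params):
            return np.array([params[n] for n in names])

        def unpack(x):
            return {n: float(v) for n, v in zip(names, x)}

        if init is None:
            # exponential start: ln H = ln(rate) + ln t
            rate = max(events.sum() / max(times.sum(), 1e-12), 1e-8)
            init = {n: 0.0 for n in names}
            init["gamma0"] = math.log(rate)
            init["gamma1"] = 1.0
    else:
        trans = dict(_TRANSFORMS[kernel])
        names = list(trans)
        if cure:
            names = ["theta"] + names

        def pack(params):
            out = []
            for n in names:
                if n == "theta":
                    out.append(_logit(float(params["theta"])))
                else:
                    out.append(trans[n][0](float(params[n])))
            return np.array(out)

        def unpack(x):
            out = {}
            for n, v in zip(names, x):
                out[n] = _expit(v) if n == "theta" else trans[n][1](float(v))
            return out

        if init is None:
            init = _default_init(kernel, times, events)
            if cure:
                init = {"theta": 0.2, **init}

    def negloglik(x):
        try:
            params = unpack(x)
            dist = _make_dist(
                family, params, time_unit,
                knots=knots if family == "rp_spline" else None,
                base_family=base_family,
            )
        except (ParameterDomainError, OverflowError):
            return 1e12
        with np.errstate(all="ignore"):
            lp = _logpdf(dist, times[is_event])
            ls = _logsf(dist, times[~is_event])
        ll = float(np.sum(lp) + np.sum(ls))
        if not np.isfinite(ll):
            return 1e12
        return -ll

    x0 = pack(init)
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0, 0.5, size=x0.size)
        res = optimize.minimize(
            negloglik, xs, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res

    params = unpack(best.x)
    loglik = -float(best.fun)
    converged = bool(best.success) and np.isfinite(loglik) and best.fun < 1e11
    dist = _make_dist(
        family, params, time_unit,
        knots=knots if family == "rp_spline" else None,
        base_family=base_family,
    )
    k = len(best.x)
    return FitResult(
        distribution=dist,
        loglik=loglik if np.isfinite(loglik) else float("-inf"),
        n_params=k,
        aic=2 * k - 2 * loglik,
        converged=converged,
    )


def select_best(fits: Iterable[FitResult]) -> FitResult:
    """Lowest-AIC converged fit; ties broken by fewer parameters, then family order."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise SelectionError("no converged fits to select from")

    def sort_key(f: FitResult):
        fam_idx = FAMILIES.index(f.distribution.family) if f.distribution.family in FAMILIES else 99
        return (f.aic, f.n_params, fam_idx)

    return min(converged, key=sort_key)
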
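"""Pseudo individual-patient data from digitized Kaplan-Meier curves.

Given digitized (time, survival) coordinates and a numbers-at-risk table, the
interval-wise algorithm solves for event and censor counts consistent with the
KM steps and the risk table, assuming censoring is spread uniformly within
each risk interval.  Event times sit on the digitized step times; censor times
are spaced deterministically, so reconstruction is fully reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

_MAX_ITER = 40


@dataclass(frozen=True)
class DigitizedKM:
    """Digitized KM curve points plus a numbers-at-risk table.

    ``points`` is an ordered list of (time, survival probability) starting at
    (0, 1); ``risk_table`` an ordered list of (time, n at risk).
    """

    points: tuple[tuple[float, float], ...]
    risk_table: tuple[tuple[float, int], ...]
    total_events: int | None = None

    def __post_init__(self):
        pts = tuple((float(t), float(s)) for t, s in self.points)
        rt = tuple((float(t), int(n)) for t, n in self.risk_table)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "risk_table", rt)
        self.validate()

    def validate(self) -> None:
        if len(self.points) < 2:
            raise ValidationError("need at least 2 digitized points")
        if not self.risk_table:
            raise ValidationError("need at least one risk-table entry")
        t = np.array([p[0] for p in self.points])
        s = np.array([p[1] for p in self.points])
        if t[0] != 0 or abs(s[0] - 1.0) > 1e-9:
            raise ValidationError("first digitized point must be (0, 1)")
        if np.any(np.diff(t) < 0):
            raise ValidationError("digitized times must be non-decreasing")
        if np.any((s < -1e-9) | (s > 1 + 1e-9)):
            raise ValidationError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(s) > 1e-9):
            raise ValidationError("survival probabilities must be non-increasing")
        rt = np.array([r[0] for r in self.risk_table])
        rn = np.array([r[1] for r in self.risk_table])
        if np.any(np.diff(rt) <= 0):
            raise ValidationError("risk-table times must be strictly increasing")
        if np.any(np.diff(rn) > 0):
            raise ValidationError("numbers at risk must be non-increasing")
        if rn[0] < 1:
            raise ValidationError("initial number at risk must be >= 1")
        if rt[0] > t[-1]:
            raise ValidationError("risk table lies outside the observation window")

    @classmethod
    def from_csv(cls, curve_path, risk_path, total_events=None) -> "DigitizedKM":
        """Read curve points (columns time, survival) and risk table (time, n_at_risk)."""
        curve = pd.read_csv(curve_path)
        risk = pd.read_csv(risk_path)
        return cls(
            points=tuple(zip(curve["time"], curve["survival"])),
            risk_table=tuple(zip(risk["time"], risk["n_at_risk"])),
            total_events=total_events,
        )


@dataclass(frozen=True)
class PseudoIPD:
    """Reconstructed event/censor times standing in for patient-level data."""

    records: tuple[tuple[float, int], ...]
    n: int = field(default=0)

    def __post_init__(self):
        recs = tuple((float(t), int(e)) for t, e in self.records)
        object.__setattr__(self, "records", recs)
        if self.n == 0:
            object.__setattr__(self, "n", len(recs))
        if self.n != len(recs):
            raise ValidationError("n must equal the number of records")
        for t, e in recs:
            if t < 0 or e not in (0, 1):
                raise ValidationError("times must be >= 0 and event flags in {0,1}")

    @property
    def times(self) -> np.ndarray:
        return np.array([r[0] for r in self.records])

    @property
    def events(self) -> np.ndarray:
        return np.array([r[1] for r in self.records])

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def to_frame(self, arm: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "event": self.events})
        if arm is not None:
            df["arm"] = arm
        return df

    def to_csv(self, path, arm: str | None = None) -> None:
        self.to_frame(arm).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, arm: str | None = None) -> "PseudoIPD":
        df = pd.read_csv(path)
        if arm is not None and "arm" in df.columns:
            df = df[df["arm"] == arm]
        return cls(records=tuple(zip(df["time"], df["event"])))


def km_curve(ipd: PseudoIPD) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit estimate of the IPD: (event times incl. 0, S values)."""
    times, events = ipd.times, ipd.events
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times[events == 1])
    s = 1.0
    out_t, out_s = [0.0], [1.0]
    n_at_risk = len(times)
    idx = 0
    for ut in uniq:
        # remove earlier exits
        while idx < len(times) and times[idx] < ut:
            n_at_risk -= 1
            idx += 1
        d = int(np.sum((times == ut) & (events == 1)))
        if n_at_risk > 0:
            s *= 1.0 - d / n_at_risk
        out_t.append(float(ut))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


def km_at(ipd: PseudoIPD, query_times) -> np.ndarray:
    """Step-function KM evaluated at arbitrary times."""
    t, s = km_curve(ipd)
    q = np.atleast_1d(np.asarray(query_times, float))
    idx = np.searchsorted(t, q, side="right") - 1
    return s[np.clip(idx, 0, len(s) - 1)]


def _spread(count: int, lo: float, hi: float) -> list[float]:
    """Deterministic uniform spread of `count` times across (lo, hi)."""
    if count <= 0:
        return []
    return [lo + (j + 0.5) * (hi - lo) / count for j in range(count)]


def reconstruct_ipd(km: DigitizedKM) -> PseudoIPD:
    """Reconstruct pseudo-IPD from a digitized KM curve and risk table.

    Returns exactly ``n`` records where ``n`` is the initial number at risk.
    Implied negative event counts are clamped to zero with a logged warning.
    When ``total_events`` is supplied, the administrative-censoring tail is
    adjusted so the reconstructed event count matches it where feasible.
    """
    t = np.array([p[0] for p in km.points])
    s = np.array([p[1] for p in km.points])
    n_pts = len(t)
    risk_t = [r[0] for r in km.risk_table]
    risk_n = [r[1] for r in km.risk_table]
    n0 = risk_n[0]

    # map risk times to the first digitized index at/after them
    lower = [int(np.searchsorted(t, rt, side="left")) for rt in risk_t]
    lower[0] = 0
    boundaries = lower + [n_pts]

    d = np.zeros(n_pts, dtype=int)          # events at point k
    cen = np.zeros(n_pts, dtype=int)        # censored in (t_k, t_{k+1})
    n_hat = np.zeros(n_pts + 1, dtype=float)
    n_hat[0] = n0
    km_prod = np.ones(n_pts)
    clamped = False

    def run_interval(i0: int, i1: int, n_censor: int, entry_n: float, entry_prod: float):
        """Recompute events/censors on clicks [i0, i1) given censor total."""
        hi = t[i1] if i1 < n_pts else t[n_pts - 1]
        lo = t[i0]
        cen_times = _spread(n_censor, lo, hi)
        nonlocal clamped
        n_cur, prod = entry_n, entry_prod
        d_loc = np.zeros(i1 - i0, dtype=int)
        c_loc = np.zeros(i1 - i0, dtype=int)
        prods = np.zeros(i1 - i0)
        for k in range(i0, i1):
            if k == 0:
                dk = 0
            elif prod <= 0 or n_cur <= 0:
                dk = 0
            else:
                dk = int(round(n_cur * (1.0 - s[k] / prod)))
                if dk < 0:
                    clamped = True
                    dk = 0
                dk = min(dk, int(n_cur))
            if n_cur > 0 and dk > 0:
                prod *= 1.0 - dk / n_cur
            next_t = t[k + 1] if k + 1 < n_pts else np.inf
            ck = sum(1 for ct in cen_times if t[k] <= ct < next_t)
            ck = min(ck, int(n_cur) - dk)
            d_loc[k - i0] = dk
            c_loc[k - i0] = ck
            prods[k - i0] = prod
            n_cur = n_cur - dk - ck
        return d_loc, c_loc, prods, n_cur

    n_intervals = len(risk_t)
    for i in range(n_intervals):
        i0, i1 = boundaries[i], boundaries[i + 1]
        if i0 >= i1:
            continue
        entry_n = n_hat[i0] if i > 0 else float(n0)
        entry_prod = km_prod[i0 - 1] if i0 > 0 else 1.0
        last = i == n_intervals - 1

        if not last:
            target = risk_n[i + 1]
            # initial censor guess from the survival ratio
            if s[i0] > 0:
                guess = int(round(entry_n * s[min(i1, n_pts - 1)] / s[i0])) - target
            else:
                guess = 0
            guess = max(0, guess)
            best = None
            for _ in range(_MAX_ITER):
                d_loc, c_loc, prods, n_exit = run_interval(i0, i1, guess, entry_n, entry_prod)
                diff = n_exit - target
                if best is None or abs(diff) < abs(best[0]):
                    best = (diff, guess, d_loc, c_loc, prods, n_exit)
                if diff == 0:
                    break
                guess = max(0, guess + int(round(diff)))
                if guess == best[1] and diff != 0:
                    break
            _, _, d_loc, c_loc, prods, n_exit = best
        else:
            # final interval: administrative censoring only (no risk info beyond)
            d_loc, c_loc, prods, n_exit = run_interval(i0, i1, 0, entry_n, entry_prod)

        d[i0:i1] = d_loc
        cen[i0:i1] = c_loc
        km_prod[i0:i1] = prods
        for k in range(i0, i1):
            n_hat[k + 1] = (n_hat[k] if k > i0 else entry_n) - d[k] - cen[k]

    if clamped:
        logger.warning("reconstruct_ipd: some implied event counts were negative; clamped to 0")

    leftover = int(round(n_hat[n_pts]))

    if km.total_events is not None:
        total_d = int(d.sum())
        shift = km.total_events - total_d
        if shift != 0:
            # move the discrepancy between the administrative tail and the
            # trailing steps' events, within feasibility
            if shift < 0:
                k = n_pts - 1
                remaining = -shift
                while k >= 0 and remaining > 0:
                    take = min(int(d[k]), remaining)
                    d[k] -= take
                    leftover += take
                    remaining -= take
                    k -= 1
            else:
                adjust = min(shift, leftover)
                d[n_pts - 1] += adjust
                leftover -= adjust
            if int(d.sum()) != km.total_events:
                logger.warning(
                    "reconstruct_ipd: could not match total_events=%s exactly (got %s)",
                    km.total_events, int(d.sum()),
                )

    records: list[tuple[float, int]] = []
    for k in range(n_pts):
        records.extend((float(t[k]), 1) for _ in range(int(d[k])))
        next_t = t[k + 1] if k + 1 < n_pts else t[k]
        records.extend((float(ct), 0) for ct in _spread(int(cen[k]), t[k], next_t))
    records.extend((float(t[-1]), 0) for _ in range(max(leftover, 0)))

    # guarantee exactly n0 records (numerical slack only)
    if len(records) > n0:
        records = records[:n0]
    while len(records) < n0:
        records.append((float(t[-1]), 0))

    records.sort(key=lambda r: (r[0], -r[1]))
    return PseudoIPD(records=tuple(records), n=n0)
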
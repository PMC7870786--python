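"""Incremental cost-effectiveness outputs and dominance classification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .exceptions import ParameterDomainError

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class CEResult:
    """Pairwise cost-effectiveness comparison at willingness-to-pay ``wtp``.

    ``icer`` is a $/QALY ratio for quadrant I/III increments, the label
    ``"dominant"``/``"dominated"`` for quadrants II/IV, and None when the
    effect increment is zero.
    """

    cost_0: float
    cost_1: float
    effect_0: float
    effect_1: float
    delta_cost: float
    delta_effect: float
    icer: Union[float, str, None]
    inhb: float
    inmb: float
    wtp: float

    @property
    def cost_effective(self) -> bool:
        # positive net benefit at the threshold (covers all four quadrants)
        return self.inmb > 0

    def summary(self, round_outputs: bool = True) -> dict:
        """Report-ready dict; costs to whole $, QALY-scale values to 3 dp."""
        icer = self.icer
        if round_outputs and isinstance(icer, float):
            icer = round(icer)
        return {
            "delta_cost": round(self.delta_cost) if round_outputs else self.delta_cost,
            "delta_effect": round(self.delta_effect, 3) if round_outputs else self.delta_effect,
            "icer": icer,
            "inhb": round(self.inhb, 3) if round_outputs else self.inhb,
            "inmb": round(self.inmb) if round_outputs else self.inmb,
            "wtp": self.wtp,
            "cost_effective": self.cost_effective,
        }


def compare(
    cost_0: float,
    effect_0: float,
    cost_1: float,
    effect_1: float,
    wtp: float,
) -> CEResult:
    """Full two-strategy comparison (index 1 vs reference 0)."""
    if wtp <= 0:
        raise ParameterDomainError("willingness-to-pay must be positive")
    dc = cost_1 - cost_0
    de = effect_1 - effect_0
    icer: Union[float, str, None]
    if de > 0 and dc < 0:
        icer = DOMINANT
    elif de < 0 and dc > 0:
        icer = DOMINATED
    elif de == 0:
        icer = None
    else:
        icer = dc / de
    return CEResult(
        cost_0=cost_0,
        cost_1=cost_1,
        effect_0=effect_0,
        effect_1=effect_1,
        delta_cost=dc,
        delta_effect=de,
        icer=icer,
        inhb=de - dc / wtp,
        inmb=de * wtp - dc,
        wtp=wtp,
    )


def evaluate(delta_cost: float, delta_effect: float, wtp: float) -> CEResult:
    """Comparison from increments alone (reference normalized to zero)."""
    return compare(0.0, 0.0, delta_cost, delta_effect, wtp)


def from_traces(trace_0, trace_1, wtp: float) -> CEResult:
    """Compare two engine traces (1 = intervention, 0 = reference)."""
    return compare(
        trace_0.total_cost, trace_0.total_qalys,
        trace_1.total_cost, trace_1.total_qalys,
        wtp,
    )
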
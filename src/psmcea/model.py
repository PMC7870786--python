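"""Two-strategy scenario container and parameter-path plumbing.

A :class:`ScenarioModel` bundles the reference arm, the intervention arm and
the shared settings, and supports setting any nested field through a dotted
path (e.g. ``"intervention.hr_pfs.value"``) — the mechanism the sensitivity
analyses use to perturb single parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, is_dataclass, replace

from .econ import CEResult, from_traces
from .engine import ModelSettings, StrategyConfig, Trace, build_trace
from .exceptions import ConfigError


@dataclass(frozen=True)
class ScenarioModel:
    """Reference (standard care) vs intervention comparison under one setting."""

    reference: StrategyConfig
    intervention: StrategyConfig
    settings: ModelSettings
    label: str = ""

    def run(self) -> tuple[Trace, Trace, CEResult]:
        trace_ref = build_trace(self.reference, self.settings)
        trace_int = build_trace(self.intervention, self.settings, reference=self.reference)
        return trace_ref, trace_int, from_traces(trace_ref, trace_int, self.settings.wtp)

    def evaluate(self) -> CEResult:
        return self.run()[2]

    def with_param(self, path: str, value) -> "ScenarioModel":
        """Return a copy with the dotted-path field replaced."""
        return _set_path(self, path, value)

    def with_params(self, assignments: dict) -> "ScenarioModel":
        model = self
        for path, value in assignments.items():
            model = _set_path(model, path, value)
        return model


def _set_path(obj, path: str, value):
    """Immutable nested update through frozen dataclasses."""
    head, _, rest = path.partition(".")
    if not hasattr(obj, head):
        raise ConfigError(f"unknown parameter path segment {head!r} on {type(obj).__name__}")
    if rest:
        child = _set_path(getattr(obj, head), rest, value)
    else:
        child = value
    if is_dataclass(obj):
        return replace(obj, **{head: child})
    clone = copy.copy(obj)
    setattr(clone, head, child)
    return clone


def get_path(obj, path: str):
    cur = obj
    for part in path.split("."):
        if not hasattr(cur, part):
            raise ConfigError(f"unknown parameter path segment {part!r} on {type(cur).__name__}")
        cur = getattr(cur, part)
    return cur
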
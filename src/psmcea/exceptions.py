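"""Exception hierarchy for psmcea."""


class PsmceaError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(PsmceaError, ValueError):
    """A distribution parameter is outside its admissible domain."""


class TimeDomainError(PsmceaError, ValueError):
    """A time argument is outside the function's domain (e.g. t < 0)."""


class UndefinedHazardError(PsmceaError, ValueError):
    """Hazard requested at a point where S(t) = 0."""


class NonIdentifiableError(PsmceaError, ValueError):
    """The likelihood cannot identify parameters (e.g. no events)."""


class SelectionError(PsmceaError, ValueError):
    """Model selection has no converged candidates."""


class ValidationError(PsmceaError, ValueError):
    """Structured input failed validation."""


class ExtrapolationError(PsmceaError, ValueError):
    """Hazard-ratio carry-forward is undefined (reference survival is 0)."""


class ConfigError(PsmceaError, ValueError):
    """Model configuration failed schema validation."""
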
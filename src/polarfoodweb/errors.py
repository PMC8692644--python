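"""Exception hierarchy."""


class PolarFoodWebError(Exception):
    """Base class for package errors."""


class ParameterError(PolarFoodWebError, ValueError):
    """A configuration or parameter value is invalid."""


class DomainError(PolarFoodWebError, ValueError):
    """An argument lies outside its mathematical domain."""


class FormatError(PolarFoodWebError, ValueError):
    """A file is malformed or incomplete."""


class IntegrationError(PolarFoodWebError, RuntimeError):
    """The integrator produced a non-finite or diverging state."""


class OptimizationError(PolarFoodWebError, RuntimeError):
    """An optimisation cannot proceed (e.g. objective never finite)."""


class StructuralError(PolarFoodWebError, KeyError):
    """Two results that must share structure (pool lists, quantities) do not."""
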
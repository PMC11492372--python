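"""Exception types raised by the nanopore model."""


class PoresigError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PoresigError, ValueError):
    """An input violates a documented precondition (non-positive
    concentration, non-positive translocation time, oversized analyte...)."""


class ConfigurationError(PoresigError, ValueError):
    """A required configuration value is missing (e.g. an ion mobility that
    has no shipped default)."""


class AmbiguityError(PoresigError, ValueError):
    """The majority ion cannot be chosen automatically (exact radius tie);
    the caller must supply an explicit override."""


class DegenerateStateError(PoresigError, ArithmeticError):
    """A derived state is degenerate (zero drift velocity, vanishing
    perturbed charge density, zero EDL capacitance)."""


class ExtractionError(PoresigError, RuntimeError):
    """Event extraction could not establish a baseline for the trace."""


class FitError(PoresigError, RuntimeError):
    """The inverse fit failed over the entire parameter grid."""
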
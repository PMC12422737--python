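"""Exception hierarchy shared across foragekit modules."""


class ForagekitError(Exception):
    """Base class for all foragekit errors."""


class ConfigurationError(ForagekitError, ValueError):
    """Invalid configuration: unknown layout, bad parameter values, etc."""


class InputDataError(ForagekitError, ValueError):
    """Malformed input data (duplicate timestamps, non-positive densities, ...)."""


class InsufficientDataError(ForagekitError, ValueError):
    """Not enough rows / labels / classes to carry out the requested fit."""


class DegenerateDataError(ForagekitError, ValueError):
    """Zero-variance or rank-deficient data where spread is required."""


class FittingError(ForagekitError, RuntimeError):
    """A model fit failed (rank deficiency, separation, missing condition)."""


class SeparationError(FittingError):
    """Perfect separation: the logistic likelihood is unbounded; use ridge."""


class NumericalError(ForagekitError, RuntimeError):
    """A numerical routine failed to converge; diagnostics in the message."""


class LookupError_(ForagekitError, KeyError):
    """Unknown condition / fixture / covariate requested."""
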
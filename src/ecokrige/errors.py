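"""Exception hierarchy shared across the package."""


class EcokrigeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(EcokrigeError, ValueError):
    """A model parameter violates its constraints (e.g. phi <= 0)."""


class InvalidInputError(EcokrigeError, ValueError):
    """Malformed or empty input data."""


class InsufficientDataError(EcokrigeError, ValueError):
    """Too few observations for the requested operation."""


class DegenerateDataError(EcokrigeError, ValueError):
    """Data cannot identify the model (n <= number of trend coefficients)."""


class FittingFailedError(EcokrigeError, RuntimeError):
    """Posterior evaluation failed on every grid cell."""


class UndefinedFitError(EcokrigeError, ValueError):
    """A regression fit is undefined (zero-variance regressor)."""


class RescaleUndefinedError(EcokrigeError, ValueError):
    """Series rescaling is undefined (reference maximum is zero)."""


class StateError(EcokrigeError, RuntimeError):
    """Operation called on an object in the wrong state (e.g. unfitted)."""
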
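"""Exception hierarchy shared across the package."""


class QiviveError(Exception):
    """Base class for all package errors."""


class DomainError(QiviveError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class DataError(QiviveError, ValueError):
    """Measured input data violate a structural requirement."""


class ConfigurationError(QiviveError, ValueError):
    """A configuration file or parameter table is invalid or incomplete."""


class SimulationError(QiviveError, RuntimeError):
    """The kinetic simulation failed (non-finite states, mass-balance breach)."""


class FitError(QiviveError, RuntimeError):
    """A model fit did not converge or is undefined for the data."""
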
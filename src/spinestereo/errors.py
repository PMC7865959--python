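"""Exception hierarchy shared across the package."""


class SpineStereoError(Exception):
    """Base class for all package errors."""


class DomainError(SpineStereoError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigError(SpineStereoError, ValueError):
    """A configuration object is inconsistent or infeasible."""


class EstimationError(SpineStereoError, RuntimeError):
    """A density or summary estimate is undefined for the given inputs."""


class DensityInfeasibleError(SpineStereoError, RuntimeError):
    """Hard-core placement could not achieve the requested density."""


class TableFormatError(SpineStereoError, ValueError):
    """A measurement table violates the documented schema or invariants."""
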
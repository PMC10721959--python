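"""Named exception types used across the pipeline.

Every validation failure raises one of these so callers (and the CLI) can
distinguish bad input from bugs.
"""


class FireabundError(Exception):
    """Base class for all package errors."""


class InputError(FireabundError):
    """Raised when raw input tables are malformed or inconsistent."""


class DegenerateInputError(FireabundError):
    """Raised when an input is structurally valid but statistically
    degenerate (e.g. a constant vector passed to a standardizer)."""


class ContractError(FireabundError):
    """Raised when an inter-module contract is violated, e.g. an
    unstandardized covariate handed to the design builder."""


class DomainError(FireabundError):
    """Raised when a numeric argument is outside the mathematical domain
    of a density or link function."""


class NumericalError(FireabundError):
    """Raised when a computation produces non-finite values."""


class InitializationError(FireabundError):
    """Raised when the sampler cannot find a finite starting state."""
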
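"""Exception hierarchy shared across the package."""


class HydrophysError(Exception):
    """Base class for all package errors."""


class ValidationError(HydrophysError, ValueError):
    """Raised when an input record, spec, or argument violates its contract.

    Messages name the offending field so CLI users can locate the problem.
    """


class ConvergenceError(HydrophysError, RuntimeError):
    """Raised when an optimiser fails and no flagged-result path exists."""
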
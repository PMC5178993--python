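"""Exception hierarchy shared across the package."""


class MetaphenoError(Exception):
    """Base class for all package errors."""


class FormatError(MetaphenoError):
    """A file does not conform to its expected dialect."""


class ValidationError(MetaphenoError):
    """Inputs violate a documented precondition or invariant."""


class UndefinedStatisticError(MetaphenoError):
    """A statistic is undefined for the given data (e.g. all-missing column)."""


class PipelineError(MetaphenoError):
    """A pipeline stage cannot proceed (e.g. QC removed every individual)."""


class ConvergenceError(MetaphenoError):
    """An iterative algorithm failed to converge after all retries."""
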
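"""Exception taxonomy shared across the package."""


class LiverRegError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(LiverRegError, ValueError):
    """Invalid parameter, schedule or keyword."""


class EmptyInputError(LiverRegError, ValueError):
    """An operation requiring nonempty input received an empty one."""


class DomainError(LiverRegError, ValueError):
    """A point fell outside the supported spatial domain."""


class GrossMisalignmentError(LiverRegError, RuntimeError):
    """Too many samples mapped outside the moving image: the current
    transform is grossly wrong and the similarity metric is meaningless."""


class DegenerateMaskError(LiverRegError, ValueError):
    """All coefficient-mask weights vanish at the evaluation points."""


class ContractViolationError(LiverRegError, ValueError):
    """A caller violated a documented input contract (e.g. an unnormalized
    histogram or mismatched landmark counts)."""


class ParseError(LiverRegError, ValueError):
    """A structured text file (landmarks, config) could not be parsed."""


class OptimizationError(LiverRegError, RuntimeError):
    """Non-finite cost or gradient during optimization; carries the trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
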
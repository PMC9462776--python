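"""Exception types shared across the package."""


class AblinkError(Exception):
    """Base class for all package-specific errors."""


class InvalidLagError(AblinkError, ValueError):
    """Raised when a T1-T2 lag is not a positive integer."""


class TrialLengthError(AblinkError, ValueError):
    """Raised when a trial is too short to contain the stimulus response."""


class ParameterError(AblinkError, ValueError):
    """Raised when a model, kernel or fit parameter is invalid."""


class DegenerateKernelError(AblinkError, ValueError):
    """Raised when a kernel has no usable shape (e.g. all-zero)."""


class PresetError(AblinkError, KeyError):
    """Raised when an unknown parameter preset is requested."""


class CriterionError(AblinkError, ValueError):
    """Raised when a consistency criterion is evaluated on unsuitable input."""
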
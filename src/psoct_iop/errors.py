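"""Exception hierarchy for the PS-OCT analysis pipeline."""


class PSOCTError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(PSOCTError, ValueError):
    """Input data violates a documented precondition (shape, sign, finiteness)."""


class ConfigurationError(PSOCTError, ValueError):
    """A parameter combination is geometrically or physically inconsistent."""


class SegmentationError(PSOCTError, RuntimeError):
    """A surface could not be detected on enough A-scans to be usable."""


class RegistrationError(PSOCTError, RuntimeError):
    """Two volumes/surfaces do not overlap enough to be registered."""


class InsufficientDataError(PSOCTError, ValueError):
    """Too few data points for the requested statistic."""


class UndefinedCorrelationError(PSOCTError, ValueError):
    """Correlation undefined (e.g. one variable is constant after ranking)."""
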
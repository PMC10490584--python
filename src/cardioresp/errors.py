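"""Exception hierarchy shared by all pipeline stages."""


class CardiorespError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CardiorespError, ValueError):
    """A parameter violates its precondition (e.g. band edge outside (0, fs/2))."""


class DegenerateInputError(CardiorespError, ValueError):
    """Input is structurally valid but too short / too flat for the operation."""


class EstimationFailureError(CardiorespError, RuntimeError):
    """A detection or estimation stage could not produce a usable result."""


class FormatError(CardiorespError, ValueError):
    """A record or annotation file could not be parsed."""
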
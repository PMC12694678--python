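"""Exception hierarchy shared across the detection modules."""


class LifesignError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(LifesignError, ValueError):
    """A caller-supplied parameter is out of its documented range."""


class InvalidInputError(LifesignError, ValueError):
    """Input data violates a precondition (empty, non-finite, too short)."""


class DegenerateDistributionError(LifesignError, ValueError):
    """All calibration samples are identical; no density can be estimated."""


class CalibrationError(LifesignError, ValueError):
    """Calibration corpus is unusable (too few samples, wrong columns)."""


class MessageFormatError(LifesignError, ValueError):
    """A telemetry message violates the 6-field wire grammar."""
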